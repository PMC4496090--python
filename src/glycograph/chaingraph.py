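"""Chain-graph (graphical Markov) models fitted as sequences of regressions.

Variables are arranged in ordered boxes, leftmost = final responses,
rightmost = intrinsic characteristics.  Each continuous non-rightmost
variable is regressed by ordinary least squares on *all* variables strictly
to its right; the explanatory set is then pruned by backward elimination
using partial F-tests between nested models, and prespecified clinically
relevant interactions are screened on top of the selected model (main
effects forced in by the hierarchy principle).  The graph is read off the
selected models: a directed edge per retained term significant at the edge
threshold, undirected edges between associated rightmost-box pairs, and a
missing edge encodes conditional independence given the selected sets.

Treatment-arm nodes are sources only: randomised assignment is independent
of everything to its right by design, so no regression is fitted for them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, ConfigurationError, DomainError

__all__ = [
    "Variable",
    "Box",
    "VariableOrdering",
    "Term",
    "RegressionFit",
    "DirectedEdge",
    "UndirectedEdge",
    "ChainGraph",
    "PredictionQuery",
    "PredictionResult",
    "validate_ordering",
    "fit_full_model",
    "select_model",
    "screen_interactions",
    "fit_response",
    "fit_all",
    "symmetric_associations",
    "build_graph",
    "variance_explained",
    "predict_outcome_ratio",
    "export_graph",
]

ROLES = ("response", "intermediate", "treatment", "intrinsic")


@dataclass(frozen=True)
class Variable:
    """Metadata for one analysis variable."""

    name: str
    vtype: str = "continuous"  # 'continuous' | 'categorical'
    reference: str | None = None
    role: str = "intermediate"

    def __post_init__(self) -> None:
        if self.vtype not in ("continuous", "categorical"):
            raise ConfigurationError(f"{self.name}: unknown type {self.vtype!r}")
        if self.role not in ROLES:
            raise ConfigurationError(f"{self.name}: unknown role {self.role!r}")
        if self.vtype == "categorical" and self.reference is None:
            raise ConfigurationError(f"{self.name}: categorical needs a reference level")


@dataclass(frozen=True)
class Box:
    variables: tuple[str, ...]
    stacked: bool = False


class VariableOrdering:
    """Ordered boxes of variables, leftmost = responses, rightmost = intrinsic."""

    def __init__(self, boxes: Sequence[Box], variables: Mapping[str, Variable]):
        self.boxes = list(boxes)
        self.variables = dict(variables)
        seen: dict[str, int] = {}
        for i, box in enumerate(self.boxes):
            for name in box.variables:
                if name in seen:
                    raise ConfigurationError(f"variable {name!r} appears in two boxes")
                seen[name] = i
        self._box_of = seen
        for name in seen:
            if name not in self.variables:
                self.variables[name] = Variable(name=name)
        last = len(self.boxes) - 1
        for name, var in self.variables.items():
            if name not in seen:
                raise ConfigurationError(f"variable {name!r} is in no box")
            if var.role == "response" and seen[name] != 0:
                raise ConfigurationError(f"response {name!r} must sit in the leftmost box")
            if var.role == "intrinsic" and seen[name] != last:
                raise ConfigurationError(f"intrinsic {name!r} must sit in the rightmost box")

    def box_of(self, name: str) -> int:
        try:
            return self._box_of[name]
        except KeyError:
            raise ConfigurationError(f"variable {name!r} not in ordering") from None

    @property
    def all_variables(self) -> list[str]:
        return [v for box in self.boxes for v in box.variables]

    @property
    def rightmost(self) -> tuple[str, ...]:
        return self.boxes[-1].variables

    def explanatory_for(self, name: str) -> list[str]:
        """All variables strictly to the right of ``name``'s box."""
        i = self.box_of(name)
        return [v for box in self.boxes[i + 1:] for v in box.variables]

    def responses(self) -> list[str]:
        """Variables for which a regression is fitted: continuous,
        non-treatment, and not in the rightmost box."""
        out = []
        for box in self.boxes[:-1]:
            for name in box.variables:
                var = self.variables[name]
                if var.role != "treatment" and var.vtype == "continuous":
                    out.append(name)
        return out


def validate_ordering(ordering: VariableOrdering, data_columns: Iterable[str]) -> VariableOrdering:
    """Check that every ordered variable maps to a data column.

    An empty rightmost box is degenerate but legal (warning only).
    """
    cols = set(data_columns)
    missing = [v for v in ordering.all_variables if v not in cols]
    if missing:
        raise ConfigurationError(f"ordering variables absent from data: {missing}")
    if not ordering.rightmost:
        warnings.warn("rightmost box is empty; no symmetric associations will be tested")
    return ordering


# ---------------------------------------------------------------------------
# Terms and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """A main effect (one variable) or a product interaction (two)."""

    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.variables) <= 2:
            raise ConfigurationError("terms are main effects or pairwise interactions")

    @property
    def name(self) -> str:
        return ":".join(self.variables)

    @property
    def is_interaction(self) -> bool:
        return len(self.variables) == 2

    @staticmethod
    def main(var: str) -> "Term":
        return Term((var,))

    @staticmethod
    def interaction(a: str, b: str) -> "Term":
        return Term(tuple(sorted((a, b))))


def _levels(data: pd.DataFrame, var: Variable) -> list[str]:
    levels = sorted(str(v) for v in data[var.name].dropna().unique())
    if var.reference not in levels:
        raise ConfigurationError(
            f"{var.name}: reference level {var.reference!r} absent from data"
        )
    return levels


def _encode_main(data: pd.DataFrame, var: Variable) -> pd.DataFrame:
    """Continuous -> one column; categorical -> dummies against the reference."""
    if var.vtype == "continuous":
        return data[[var.name]].astype(float)
    cols = {}
    series = data[var.name].astype(str)
    for level in _levels(data, var):
        if level == var.reference:
            continue
        cols[f"{var.name}[{level}]"] = (series == level).astype(float)
    return pd.DataFrame(cols, index=data.index)


def build_design(
    data: pd.DataFrame, ordering: VariableOrdering, terms: Sequence[Term]
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, float]]:
    """Design matrix (with intercept), term-name -> columns map, and the
    product-centring constants.

    Product columns are formed from *mean-centred* continuous components
    (dummy columns stay 0/1).  Centring leaves the model span and the
    interaction coefficient unchanged but keeps products near-orthogonal to
    their main effects, so a retained interaction does not mask its mains;
    a main-effect coefficient is then the effect at the sample mean of any
    interaction partners.
    """
    pieces = [pd.Series(1.0, index=data.index, name="Intercept").to_frame()]
    term_cols: dict[str, list[str]] = {}
    encoded_cache: dict[str, pd.DataFrame] = {}
    product_centers: dict[str, float] = {}

    def enc(varname: str) -> pd.DataFrame:
        if varname not in encoded_cache:
            encoded_cache[varname] = _encode_main(data, ordering.variables[varname])
        return encoded_cache[varname]

    def enc_centred(varname: str) -> pd.DataFrame:
        block = enc(varname)
        if ordering.variables[varname].vtype == "continuous":
            center = float(block[varname].mean())
            product_centers[varname] = center
            block = block - center
        return block

    for term in terms:
        if not term.is_interaction:
            block = enc(term.variables[0])
        else:
            a, b = (enc_centred(v) for v in term.variables)
            cols = {}
            for ca in a.columns:
                for cb in b.columns:
                    cols[f"{ca}:{cb}"] = a[ca] * b[cb]
            block = pd.DataFrame(cols, index=data.index)
        term_cols[term.name] = list(block.columns)
        pieces.append(block)
    X = pd.concat(pieces, axis=1)
    if X.columns.has_duplicates:
        raise ConfigurationError("duplicate design columns (term listed twice?)")
    return X, term_cols, product_centers


# ---------------------------------------------------------------------------
# OLS fitting
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    """A fitted least-squares model for one response.

    ``params`` holds per-design-column coefficient, standard error (from the
    unbiased residual-variance estimate), t value and two-sided p value.
    ``term_p`` holds per-*term* p values: the t-test p for single-column
    terms and the partial-F p (refit without the block) for dummy blocks.
    """

    response: str
    terms: tuple[Term, ...]
    params: pd.DataFrame
    term_p: dict[str, float]
    term_cols: dict[str, list[str]]
    n: int
    rss: float
    tss: float
    df_resid: int
    r_squared: float
    sigma2: float
    col_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    product_centers: dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> Term | None:
        for t in self.terms:
            if t.name == name:
                return t
        return None

    def coefficients_table(self) -> pd.DataFrame:
        tab = self.params.copy()
        tab.insert(0, "response", self.response)
        return tab


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the columns with (numerically) vanishing pivots
        _, r, piv = _pivoted_qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[piv[i]] for i in range(len(diag), X.shape[1])]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {sorted(set(map(str, aliased)))}",
            aliased=sorted(set(map(str, aliased))),
        )


def _pivoted_qr(arr):
    from scipy.linalg import qr

    return qr(arr, mode="economic", pivoting=True)


def _ols(y: pd.Series, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()


def _fit_terms(
    response: str,
    terms: Sequence[Term],
    data: pd.DataFrame,
    ordering: VariableOrdering,
) -> RegressionFit:
    """Fit ``response ~ terms`` on ``data`` (already complete-case)."""
    y = data[response].astype(float)
    X, term_cols, product_centers = build_design(data, ordering, terms)
    if len(data) < X.shape[1] + 2:
        raise DomainError(
            f"{response}: {len(data)} complete cases for {X.shape[1]} parameters"
        )
    _check_rank(X)
    res = _ols(y, X)
    params = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=X.columns,
    )
    tss = float(((y - y.mean()) ** 2).sum())
    fit = RegressionFit(
        response=response,
        terms=tuple(terms),
        params=params,
        term_p={},
        term_cols=term_cols,
        n=len(data),
        rss=float(res.ssr),
        tss=tss,
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared) if tss > 0 else 0.0,
        sigma2=float(res.ssr / res.df_resid),
        col_ranges={
            c: (float(X[c].min()), float(X[c].max())) for c in X.columns if c != "Intercept"
        },
        product_centers=product_centers,
    )
    fit.term_p = _term_pvalues(fit, data, ordering)
    return fit


def partial_f_test(
    rss_reduced: float, rss_full: float, df_drop: int, df_resid_full: int
) -> tuple[float, float]:
    """Partial F statistic and p value comparing nested OLS fits."""
    if df_drop < 1 or df_resid_full < 1:
        raise DomainError("invalid degrees of freedom for a partial F test")
    num = max(rss_reduced - rss_full, 0.0) / df_drop
    den = rss_full / df_resid_full
    if den == 0:
        return float("inf"), 0.0
    f = num / den
    return f, float(stats.f.sf(f, df_drop, df_resid_full))


def _term_pvalues(
    fit: RegressionFit, data: pd.DataFrame, ordering: VariableOrdering
) -> dict[str, float]:
    out = {}
    for term in fit.terms:
        cols = fit.term_cols[term.name]
        if len(cols) == 1:
            out[term.name] = float(fit.params.loc[cols[0], "p"])
        else:
            reduced_terms = [t for t in fit.terms if t.name != term.name]
            y = data[fit.response].astype(float)
            Xr, _, _ = build_design(data, ordering, reduced_terms)
            res_r = _ols(y, Xr)
            _, p = partial_f_test(float(res_r.ssr), fit.rss, len(cols), fit.df_resid)
            out[term.name] = p
    return out


def complete_cases(
    response: str, ordering: VariableOrdering, data: pd.DataFrame
) -> pd.DataFrame:
    """Rows complete on the response and its full explanatory set.

    The complete-case set is fixed from the *full* right-hand variable set
    so every nested comparison for this response uses identical rows.
    """
    cols = [response] + ordering.explanatory_for(response)
    return data.dropna(subset=[c for c in cols if c in data.columns])


def fit_full_model(
    response: str, ordering: VariableOrdering, data: pd.DataFrame
) -> RegressionFit:
    """OLS of ``response`` on every variable strictly to its right."""
    if ordering.box_of(response) == len(ordering.boxes) - 1:
        raise ConfigurationError(f"{response!r} sits in the rightmost box")
    cc = complete_cases(response, ordering, data)
    terms = [Term.main(v) for v in ordering.explanatory_for(response)]
    return _fit_terms(response, terms, cc, ordering)


def select_model(
    full: RegressionFit,
    data: pd.DataFrame,
    ordering: VariableOrdering,
    selection_alpha: float = 0.05,
    forced: Sequence[str] = (),
) -> RegressionFit:
    """Backward elimination by partial F-tests.

    Repeatedly refit without each droppable term and remove the one whose
    nested-comparison p value is largest, while it exceeds
    ``selection_alpha``.  Dummy blocks are dropped whole.  Ties are broken
    towards the smaller minimum absolute t statistic within the term, then
    lexicographically.  Returns the final fit (possibly intercept-only)
    refitted on the selected terms.
    """
    cc = complete_cases(full.response, ordering, data)
    current = full
    forced = set(forced)
    while True:
        droppable = [t for t in current.terms if t.name not in forced]
        if not droppable:
            break
        candidates = []
        for term in droppable:
            p = current.term_p[term.name]
            cols = current.term_cols[term.name]
            min_abs_t = float(np.abs(current.params.loc[cols, "t"]).min())
            candidates.append((p, min_abs_t, term.name, term))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        worst_p, _, _, worst = candidates[0]
        if worst_p <= selection_alpha:
            break
        remaining = [t for t in current.terms if t.name != worst.name]
        current = _fit_terms(full.response, remaining, cc, ordering)
    return current


def screen_interactions(
    selected: RegressionFit,
    candidate_pairs: Sequence[tuple[str, str]],
    data: pd.DataFrame,
    ordering: VariableOrdering,
    selection_alpha: float = 0.05,
) -> RegressionFit:
    """Test prespecified product terms against the selected model.

    Each candidate interaction is compared by a nested F-test between the
    current model augmented with the pair's main effects and the same model
    plus the product term; significant products are added greedily (most
    significant first), with their main effects forced in (hierarchy
    principle).
    """
    response = selected.response
    rhs = set(ordering.explanatory_for(response))
    for a, b in candidate_pairs:
        if response in (a, b):
            raise ConfigurationError(f"interaction candidate references the response {response!r}")
        if a not in rhs or b not in rhs:
            raise ConfigurationError(
                f"interaction candidate ({a}, {b}) not within {response!r}'s explanatory set"
            )
    cc = complete_cases(response, ordering, data)
    current = selected
    remaining = [Term.interaction(a, b) for a, b in candidate_pairs]
    while remaining:
        scored = []
        for term in remaining:
            base_terms = list(current.terms)
            for v in term.variables:
                if all(t.name != v for t in base_terms):
                    base_terms.append(Term.main(v))
            with_term = base_terms + [term]
            base_fit = _fit_terms(response, base_terms, cc, ordering)
            aug_fit = _fit_terms(response, with_term, cc, ordering)
            q = len(aug_fit.term_cols[term.name])
            _, p = partial_f_test(base_fit.rss, aug_fit.rss, q, aug_fit.df_resid)
            scored.append((p, term.name, term, aug_fit))
        scored.sort(key=lambda s: (s[0], s[1]))
        best_p, _, best_term, best_fit = scored[0]
        if best_p >= selection_alpha:
            break
        current = best_fit
        remaining = [t for t in remaining if t.name != best_term.name]
    return current


def fit_response(
    response: str,
    ordering: VariableOrdering,
    data: pd.DataFrame,
    selection_alpha: float = 0.05,
    interaction_candidates: Sequence[tuple[str, str]] = (),
) -> RegressionFit:
    """Full model -> backward elimination -> interaction screening."""
    full = fit_full_model(response, ordering, data)
    selected = select_model(full, data, ordering, selection_alpha)
    if interaction_candidates:
        selected = screen_interactions(
            selected, interaction_candidates, data, ordering, selection_alpha
        )
    return selected


def fit_all(
    ordering: VariableOrdering,
    data: pd.DataFrame,
    selection_alpha: float = 0.05,
    interaction_candidates: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> dict[str, RegressionFit]:
    """One selected model per modelled (continuous, non-treatment) response."""
    interaction_candidates = interaction_candidates or {}
    fits = {}
    for response in ordering.responses():
        fits[response] = fit_response(
            response,
            ordering,
            data,
            selection_alpha,
            interaction_candidates.get(response, ()),
        )
    return fits


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectedEdge:
    """source -> target with its partial regression coefficient.

    For dummy-block sources (categorical variables) ``coef``/``se`` are the
    per-level values keyed by design column; ``p`` is the block partial-F p.
    Interaction edges carry both source variables in ``sources``.
    """

    sources: tuple[str, ...]
    target: str
    p: float
    coef: float | None = None
    se: float | None = None
    levels: tuple[tuple[str, float, float], ...] = ()
    kind: str = "main"  # 'main' | 'interaction'

    @property
    def key(self) -> tuple[str, str]:
        return (":".join(self.sources), self.target)


@dataclass(frozen=True)
class UndirectedEdge:
    a: str
    b: str
    statistic: float
    p: float
    test: str

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))  # type: ignore[return-value]


@dataclass
class ChainGraph:
    """The fitted association graph over the ordered boxes."""

    boxes: list[Box]
    variables: dict[str, Variable]
    directed_edges: list[DirectedEdge]
    undirected_edges: list[UndirectedEdge]
    edge_alpha: float = 0.10

    @property
    def nodes(self) -> list[str]:
        return [v for box in self.boxes for v in box.variables]

    def directed_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.directed_edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for i, box in enumerate(self.boxes):
            for v in box.variables:
                g.add_node(v, box=i)
        for e in self.directed_edges:
            for s in e.sources:
                g.add_edge(s, e.target, coef=e.coef, p=e.p, kind=e.kind)
        for e in self.undirected_edges:
            g.add_edge(e.a, e.b, p=e.p, kind="undirected")
        return g

    def to_json(self) -> str:
        payload = {
            "boxes": [
                {"variables": list(b.variables), "stacked": b.stacked} for b in self.boxes
            ],
            "edge_alpha": self.edge_alpha,
            "directed_edges": [
                {
                    "sources": list(e.sources),
                    "target": e.target,
                    "kind": e.kind,
                    "coef": e.coef,
                    "se": e.se,
                    "p": e.p,
                    "levels": [list(l) for l in e.levels],
                }
                for e in self.directed_edges
            ],
            "undirected_edges": [
                {"a": e.a, "b": e.b, "statistic": e.statistic, "p": e.p, "test": e.test}
                for e in self.undirected_edges
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_dot(self, style: Mapping[str, str] | None = None) -> str:
        return export_graph(self, style)


def symmetric_associations(
    ordering: VariableOrdering, data: pd.DataFrame, edge_alpha: float = 0.10
) -> list[UndirectedEdge]:
    """Marginal association tests between every rightmost-box pair.

    Continuous-continuous pairs use the Pearson correlation t-test,
    continuous-categorical a one-way F-test, categorical pairs a chi-square
    test of independence.  Pairs significant at ``edge_alpha`` receive an
    undirected edge.
    """
    names = list(ordering.rightmost)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            va, vb = ordering.variables[a], ordering.variables[b]
            sub = data[[a, b]].dropna()
            if va.vtype == "continuous" and vb.vtype == "continuous":
                if np.ptp(sub[a]) == 0 or np.ptp(sub[b]) == 0:
                    continue
                r, p = stats.pearsonr(sub[a], sub[b])
                stat, test = float(r), "pearson"
            elif va.vtype == "categorical" and vb.vtype == "categorical":
                table = pd.crosstab(sub[a], sub[b])
                chi2, p, _, _ = stats.chi2_contingency(table)
                stat, test = float(chi2), "chi2"
            else:
                cont, cat = (a, b) if va.vtype == "continuous" else (b, a)
                groups = [g[cont].to_numpy() for _, g in sub.groupby(cat, observed=True)]
                if len(groups) < 2:
                    continue
                f, p = stats.f_oneway(*groups)
                stat, test = float(f), "anova"
            if p < edge_alpha:
                edges.append(UndirectedEdge(a=a, b=b, statistic=stat, p=float(p), test=test))
    return edges


def build_graph(
    fits: Mapping[str, RegressionFit],
    undirected_edges: Sequence[UndirectedEdge],
    ordering: VariableOrdering,
    edge_alpha: float = 0.10,
) -> ChainGraph:
    """Assemble the chain graph from the selected regressions.

    A directed edge is drawn for every retained term whose p value is below
    ``edge_alpha``; interaction terms become distinct dash-dot edges.  Edges
    always point leftward in the ordering by construction.
    """
    known = set(ordering.all_variables)
    edges: list[DirectedEdge] = []
    for response in sorted(fits):
        fit = fits[response]
        if response not in known:
            raise ConfigurationError(f"fit response {response!r} outside the ordering")
        for term in fit.terms:
            for v in term.variables:
                if v not in known:
                    raise ConfigurationError(f"fit term variable {v!r} outside the ordering")
            p = fit.term_p[term.name]
            if p >= edge_alpha:
                continue
            cols = fit.term_cols[term.name]
            if len(cols) == 1:
                coef = float(fit.params.loc[cols[0], "coef"])
                se = float(fit.params.loc[cols[0], "se"])
                levels = ()
            else:
                coef = se = None
                levels = tuple(
                    (c, float(fit.params.loc[c, "coef"]), float(fit.params.loc[c, "se"]))
                    for c in cols
                )
            edges.append(
                DirectedEdge(
                    sources=term.variables,
                    target=response,
                    p=float(p),
                    coef=coef,
                    se=se,
                    levels=levels,
                    kind="interaction" if term.is_interaction else "main",
                )
            )
    return ChainGraph(
        boxes=list(ordering.boxes),
        variables=dict(ordering.variables),
        directed_edges=edges,
        undirected_edges=list(undirected_edges),
        edge_alpha=edge_alpha,
    )


def variance_explained(fit: RegressionFit) -> float:
    """Unadjusted R-squared (1 - RSS/TSS) of the selected model."""
    if fit.tss <= 0:
        raise DomainError("total variance is zero; R-squared undefined")
    return 1.0 - fit.rss / fit.tss


# ---------------------------------------------------------------------------
# Path-based prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionQuery:
    """Covariate values at which to evaluate a fitted log-ratio model."""

    target: str
    values: dict[str, float | str]


@dataclass
class PredictionResult:
    log_ratio: float
    ratio: float
    percent_change: float
    extrapolated: list[str]


def predict_outcome_ratio(fit: RegressionFit, query: PredictionQuery) -> PredictionResult:
    """Evaluate the linear predictor at a query point and exponentiate.

    The fitted response is a log final/baseline ratio, so the exponentiated
    linear predictor is the predicted ratio and ``100 * (ratio - 1)`` the
    percent change.  Query points outside the observed covariate range are
    flagged as extrapolations (warning, not error).
    """
    if query.target != fit.response:
        raise ConfigurationError(
            f"query targets {query.target!r} but fit is for {fit.response!r}"
        )
    needed = {v for t in fit.terms for v in t.variables}
    missing = sorted(needed - set(query.values))
    if missing:
        raise ConfigurationError(f"query missing covariates {missing}")

    cols: dict[str, float] = {"Intercept": 1.0}
    for term in fit.terms:
        for col in fit.term_cols[term.name]:
            cols[col] = _design_value(col, query.values, fit.product_centers)
    lp = float(
        sum(cols[c] * fit.params.loc[c, "coef"] for c in fit.params.index if c in cols)
    )
    extrapolated = []
    for col, value in cols.items():
        rng = fit.col_ranges.get(col)
        if rng and not (rng[0] - 1e-12 <= value <= rng[1] + 1e-12):
            extrapolated.append(col)
    if extrapolated:
        warnings.warn(f"query extrapolates beyond the observed range of {extrapolated}")
    ratio = float(np.exp(lp))
    return PredictionResult(
        log_ratio=lp,
        ratio=ratio,
        percent_change=100.0 * (ratio - 1.0),
        extrapolated=extrapolated,
    )


def _design_value(
    col: str, values: Mapping[str, float | str], product_centers: Mapping[str, float]
) -> float:
    """Evaluate one design column (possibly a centred product) at a query point."""
    pieces = col.split(":")
    total = 1.0
    for piece in pieces:
        if "[" in piece:
            var, level = piece[:-1].split("[", 1)
            total *= 1.0 if str(values[var]) == level else 0.0
        else:
            value = float(values[piece])  # type: ignore[arg-type]
            if len(pieces) > 1:
                value -= product_centers.get(piece, 0.0)
            total *= value
    return total


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def _fmt_label(coef, se, p) -> str:
    if coef is None:
        return f"p={p:.3g}"
    return f"{coef:.4g} ({se:.3g}), p={p:.3g}"


def export_graph(graph: ChainGraph, style: Mapping[str, str] | None = None) -> str:
    """Deterministic DOT rendering of a chain graph.

    Directed edges are arrows, symmetric associations undirected lines
    (``dir=none``), interaction edges dash-dot styled from a synthetic
    ``a:b`` product node.  Output is byte-identical for identical input.
    """
    style = dict(style or {})
    node_shape = style.get("node_shape", "box")
    lines = [
        "digraph chain_graph {",
        "  rankdir=RL;",
        f"  node [shape={node_shape}];",
    ]
    ordered_nodes = sorted(
        graph.nodes, key=lambda v: (next(i for i, b in enumerate(graph.boxes) if v in b.variables), v)
    )
    for v in ordered_nodes:
        lines.append(f'  "{v}";')
    interaction_nodes = sorted(
        {":".join(e.sources) for e in graph.directed_edges if e.kind == "interaction"}
    )
    for v in interaction_nodes:
        lines.append(f'  "{v}" [shape=point, xlabel="{v}"];')
    for e in sorted(graph.directed_edges, key=lambda e: (e.target, ":".join(e.sources))):
        src = ":".join(e.sources)
        label = _fmt_label(e.coef, e.se, e.p)
        attrs = f'label="{label}"'
        if e.kind == "interaction":
            attrs += ', style="dashed", arrowhead="vee"'
        lines.append(f'  "{src}" -> "{e.target}" [{attrs}];')
    for e in sorted(graph.undirected_edges, key=lambda e: e.key):
        lines.append(
            f'  "{e.a}" -> "{e.b}" [dir=none, label="p={e.p:.3g}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
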