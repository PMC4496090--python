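"""Genotype ingestion, quality control, and the T2DM genetic predisposition score.

The analysis works from a small candidate panel of SNPs previously associated
with type 2 diabetes or fasting glucose in GWAS.  Genotypes are carried as
risk-allele counts (0, 1 or 2 copies of the allele associated with higher
disease incidence or higher fasting glucose).  The module provides

* per-SNP call-rate filtering and per-individual missingness filtering,
* a Hardy-Weinberg equilibrium log likelihood-ratio (G) test with a
  Bonferroni-corrected cut-off,
* composite linkage-disequilibrium r-squared for same-locus SNP pairs,
* mean-count imputation of sporadic missing genotypes, and
* the unweighted genetic predisposition score (GPS): the summed risk-allele
  count across the retained panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CannotImputeError,
    DomainError,
    EmptyPanelError,
    IdentifierError,
    SchemaError,
    StrandError,
)

__all__ = [
    "SnpRecord",
    "SnpPanel",
    "GenotypeMatrix",
    "QcReport",
    "GpsVector",
    "HweResult",
    "snp_call_rate",
    "apply_snp_qc",
    "apply_individual_qc",
    "hwe_lrt",
    "hwe_qc",
    "bonferroni_cutoff",
    "ld_r2",
    "same_locus_ld",
    "impute_missing_mean",
    "compute_gps",
    "read_panel",
    "read_genotype_csv",
    "read_plink_raw",
    "read_vcf",
]

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that cannot be disambiguated across strand flips
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

SOURCE_TRAITS = ("T2DM", "fasting_glucose")


@dataclass(frozen=True)
class SnpRecord:
    """One panel SNP: identity, locus, and risk-allele orientation.

    ``proxy_r2`` is the LD between a proxy SNP and the lead GWAS SNP it
    stands in for; when present it must exceed 0.9 (the proxy criterion).
    ``weight`` defaults to 1 (unweighted score); a per-SNP weight column is
    accepted but the score remains a plain allele count by default.
    """

    snp_id: str
    locus: str
    risk_allele: str
    other_allele: str
    source_trait: str
    proxy_r2: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise SchemaError(
                f"{self.snp_id}: alleles must be one of A/C/G/T, got "
                f"{self.risk_allele!r}/{self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise SchemaError(f"{self.snp_id}: risk and other allele are identical")
        if self.source_trait not in SOURCE_TRAITS:
            raise SchemaError(
                f"{self.snp_id}: source_trait must be one of {SOURCE_TRAITS}"
            )
        if self.proxy_r2 is not None and not 0.9 < self.proxy_r2 <= 1.0:
            raise SchemaError(
                f"{self.snp_id}: proxy_r2 must lie in (0.9, 1], got {self.proxy_r2}"
            )

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be inferred."""
        return frozenset((self.risk_allele, self.other_allele)) in AMBIGUOUS_PAIRS


class SnpPanel:
    """An ordered collection of :class:`SnpRecord` with unique ids."""

    def __init__(self, records: Iterable[SnpRecord]):
        self.records = tuple(records)
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate snp_ids in panel: {dupes}")
        self._by_id = {r.snp_id: r for r in self.records}

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __getitem__(self, snp_id: str) -> SnpRecord:
        try:
            return self._by_id[snp_id]
        except KeyError:
            raise IdentifierError(f"unknown snp_id {snp_id!r}") from None

    def __iter__(self):
        return iter(self.records)

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        return SnpPanel(self[s] for s in snp_ids)

    def loci(self) -> dict[str, list[str]]:
        """Map locus -> snp_ids, preserving panel order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.locus, []).append(r.snp_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "locus": [r.locus for r in self.records],
                "risk_allele": [r.risk_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "source_trait": [r.source_trait for r in self.records],
                "proxy_r2": [r.proxy_r2 for r in self.records],
                "weight": [r.weight for r in self.records],
            }
        )


class GenotypeMatrix:
    """Individuals x SNPs risk-allele counts.

    Internally a float DataFrame (individuals on the index, snp_ids as
    columns); missing genotypes are NaN.  Raw matrices contain only
    {0, 1, 2}; after mean imputation cells may be fractional, recorded via
    ``imputed``.
    """

    def __init__(self, counts: pd.DataFrame, imputed: bool = False):
        counts = counts.astype(float)
        if counts.index.has_duplicates:
            raise SchemaError("duplicate individual identifiers")
        if counts.columns.has_duplicates:
            raise SchemaError("duplicate snp_id columns")
        values = counts.to_numpy()
        finite = values[np.isfinite(values)]
        if imputed:
            if ((finite < 0) | (finite > 2)).any():
                raise SchemaError("allele counts must lie in [0, 2]")
        elif not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise SchemaError("raw allele counts must be 0, 1, 2 or missing")
        self.counts = counts
        self.imputed = imputed

    # -- basic accessors -------------------------------------------------
    @property
    def individuals(self) -> list:
        return list(self.counts.index)

    @property
    def snps(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def n_missing_per_individual(self) -> pd.Series:
        return self.counts.isna().sum(axis=1)

    def n_missing_per_snp(self) -> pd.Series:
        return self.counts.isna().sum(axis=0)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(hom-other, het, hom-risk) counts for a raw (unimputed) SNP."""
        col = self._column(snp_id).dropna()
        return (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )

    def _column(self, snp_id: str) -> pd.Series:
        if snp_id not in self.counts.columns:
            raise IdentifierError(f"unknown snp_id {snp_id!r}")
        return self.counts[snp_id]

    def restrict_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.counts.columns]
        if missing:
            raise IdentifierError(f"unknown snp_ids {missing}")
        return GenotypeMatrix(self.counts[list(snp_ids)], imputed=self.imputed)

    def restrict_individuals(self, ids: Sequence) -> "GenotypeMatrix":
        return GenotypeMatrix(self.counts.loc[list(ids)], imputed=self.imputed)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index_label="id")


@dataclass
class QcReport:
    """Machine-readable record of a genotype QC pass."""

    call_rates: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    excluded_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "call_rate"])
    )
    excluded_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["individual", "n_missing"])
    )
    hwe_results: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["snp_id", "statistic", "p_value", "degenerate", "excluded"]
        )
    )
    ld_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["locus", "snp_a", "snp_b", "r2"])
    )

    def merge(self, other: "QcReport") -> "QcReport":
        def cat(a, b):
            if len(a) == 0:
                return b.copy()
            if len(b) == 0:
                return a.copy()
            return pd.concat([a, b], ignore_index=True)

        merged = QcReport()
        merged.call_rates = other.call_rates if len(other.call_rates) else self.call_rates
        merged.excluded_snps = cat(self.excluded_snps, other.excluded_snps)
        merged.excluded_individuals = cat(
            self.excluded_individuals, other.excluded_individuals
        )
        merged.hwe_results = cat(self.hwe_results, other.hwe_results)
        merged.ld_pairs = cat(self.ld_pairs, other.ld_pairs)
        return merged

    def write_tsv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.excluded_snps.to_csv(directory / "excluded_snps.tsv", sep="\t", index=False)
        self.excluded_individuals.to_csv(
            directory / "excluded_individuals.tsv", sep="\t", index=False
        )
        self.hwe_results.to_csv(directory / "hwe_results.tsv", sep="\t", index=False)
        self.ld_pairs.to_csv(directory / "ld_pairs.tsv", sep="\t", index=False)

    def log_lines(self) -> list[str]:
        lines = [
            f"SNPs excluded for low call rate: {len(self.excluded_snps)}",
        ]
        for _, row in self.excluded_snps.iterrows():
            lines.append(f"  {row['snp_id']}: call rate {row['call_rate']:.4f}")
        lines.append(f"individuals excluded for missingness: {len(self.excluded_individuals)}")
        if len(self.hwe_results):
            n_fail = int(self.hwe_results["excluded"].sum())
            lines.append(f"SNPs excluded for HWE departure: {n_fail}")
            n_deg = int(self.hwe_results["degenerate"].sum())
            if n_deg:
                lines.append(f"  monomorphic SNPs reported (not excluded): {n_deg}")
        for _, row in self.ld_pairs.iterrows():
            lines.append(
                f"LD within {row['locus']}: {row['snp_a']} vs {row['snp_b']} "
                f"r2={row['r2']:.3f}"
            )
        return lines


@dataclass
class GpsVector:
    """Per-individual genetic predisposition score.

    Scores are non-negative and bounded by ``2 * n_snps_used`` (fractional
    values arise from mean imputation).
    """

    scores: pd.Series
    n_snps_used: int

    def __post_init__(self) -> None:
        lo, hi = float(self.scores.min()), float(self.scores.max())
        if lo < 0 or hi > 2 * self.n_snps_used + 1e-9:
            raise DomainError(
                f"scores must lie in [0, {2 * self.n_snps_used}], "
                f"observed range [{lo}, {hi}]"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.scores.index, "gps": self.scores.to_numpy()})


@dataclass(frozen=True)
class HweResult:
    statistic: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def snp_call_rate(matrix: GenotypeMatrix, snp_id: str) -> float:
    """Fraction of individuals with a non-missing genotype at ``snp_id``."""
    col = matrix._column(snp_id)
    if len(col) == 0:
        raise DomainError("call rate undefined for an empty cohort")
    return float(col.notna().sum() / len(col))


def apply_snp_qc(
    matrix: GenotypeMatrix, call_rate_threshold: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose call rate falls below ``call_rate_threshold``.

    SNPs with call rate >= threshold are retained (the exclusion rule is
    strictly "below threshold").
    """
    if not 0 < call_rate_threshold <= 1:
        raise DomainError("call_rate_threshold must lie in (0, 1]")
    rates = pd.Series(
        {s: snp_call_rate(matrix, s) for s in matrix.snps}, name="call_rate"
    )
    keep = [s for s in matrix.snps if rates[s] >= call_rate_threshold]
    dropped = [s for s in matrix.snps if s not in keep]
    if not keep:
        raise EmptyPanelError("call-rate filter excluded every SNP")
    report = QcReport(
        call_rates=rates,
        excluded_snps=pd.DataFrame(
            {"snp_id": dropped, "call_rate": [rates[s] for s in dropped]}
        ),
    )
    return matrix.restrict_snps(keep), report


def apply_individual_qc(
    matrix: GenotypeMatrix, max_failed: int = 3
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop individuals with >= ``max_failed`` missing genotypes."""
    if max_failed < 1:
        raise DomainError("max_failed must be >= 1")
    n_missing = matrix.n_missing_per_individual()
    keep = n_missing.index[n_missing < max_failed]
    dropped = n_missing.index[n_missing >= max_failed]
    report = QcReport(
        excluded_individuals=pd.DataFrame(
            {
                "individual": list(dropped),
                "n_missing": [int(n_missing[i]) for i in dropped],
            }
        )
    )
    return matrix.restrict_individuals(keep), report


def hwe_lrt(n_aa: int, n_ab: int, n_bb: int) -> HweResult:
    """Hardy-Weinberg log likelihood-ratio chi-square test (1 df).

    ``G = 2 * sum O * ln(O / E)`` over the three genotype classes, with
    expected counts from the maximum-likelihood allele frequency
    ``p = (2 n_aa + n_ab) / 2n``.  Zero observed classes contribute nothing.
    A monomorphic sample (one allele absent) is flagged degenerate and
    returns statistic 0.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise DomainError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise DomainError("at least one genotype observation required")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(0.0, 1.0, degenerate=True)
    expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p))
    stat = 2.0 * sum(
        o * math.log(o / e) for o, e in zip(counts, expected) if o > 0
    )
    stat = max(stat, 0.0)
    return HweResult(stat, float(stats.chi2.sf(stat, df=1)))


def bonferroni_cutoff(alpha: float, m: int) -> float:
    """Per-test significance cut-off ``alpha / m`` for ``m`` tests."""
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    if m < 1:
        raise DomainError("m must be >= 1")
    return alpha / m


def hwe_qc(
    matrix: GenotypeMatrix, alpha: float = 0.05, n_tests: int | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Evaluate the HWE G-test per SNP and exclude departures.

    The cut-off is ``alpha / n_tests`` (Bonferroni); ``n_tests`` defaults to
    the current panel size.  Monomorphic SNPs are reported as degenerate but
    never auto-excluded.
    """
    m = n_tests if n_tests is not None else len(matrix.snps)
    cutoff = bonferroni_cutoff(alpha, m)
    rows = []
    keep = []
    for snp in matrix.snps:
        res = hwe_lrt(*matrix.genotype_counts(snp))
        excluded = (not res.degenerate) and res.p_value < cutoff
        rows.append(
            {
                "snp_id": snp,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
                "excluded": excluded,
            }
        )
        if not excluded:
            keep.append(snp)
    if not keep:
        raise EmptyPanelError("HWE filter excluded every SNP")
    report = QcReport(hwe_results=pd.DataFrame(rows))
    return matrix.restrict_snps(keep), report


def ld_r2(geno_a: Sequence[float], geno_b: Sequence[float]) -> float:
    """Composite LD: squared Pearson correlation of two allele-count vectors.

    Computed over complete pairs; haplotype phase is not required.  Constant
    vectors have undefined LD.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("genotype vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise DomainError("need at least 2 complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("LD undefined for a constant genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def same_locus_ld(matrix: GenotypeMatrix, panel: SnpPanel) -> pd.DataFrame:
    """r2 for every pair of panel SNPs sharing a locus (e.g. CDKN2B pairs)."""
    rows = []
    for locus, snp_ids in panel.loci().items():
        present = [s for s in snp_ids if s in matrix.counts.columns]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                rows.append(
                    {
                        "locus": locus,
                        "snp_a": present[i],
                        "snp_b": present[j],
                        "r2": ld_r2(
                            matrix.counts[present[i]], matrix.counts[present[j]]
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=["locus", "snp_a", "snp_b", "r2"])


def impute_missing_mean(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell by the SNP's mean observed allele count."""
    counts = matrix.counts.copy()
    for snp in counts.columns:
        col = counts[snp]
        if col.isna().all():
            raise CannotImputeError(f"{snp}: no observed calls to impute from")
        if col.isna().any():
            counts[snp] = col.fillna(col.mean())
    return GenotypeMatrix(counts, imputed=True)


def compute_gps(matrix: GenotypeMatrix, panel: SnpPanel | None = None) -> GpsVector:
    """Sum risk-allele counts across SNPs for each individual.

    Requires a fully imputed matrix (no missing cells).  If ``panel`` is
    given and carries non-unit weights, a weighted sum is returned instead;
    the default is the plain (unweighted) count.
    """
    if matrix.counts.isna().any().any():
        raise DomainError("matrix contains missing cells; impute before scoring")
    if panel is not None:
        weights = np.array([panel[s].weight for s in matrix.snps])
    else:
        weights = np.ones(len(matrix.snps))
    scores = pd.Series(
        matrix.counts.to_numpy() @ weights, index=matrix.counts.index, name="gps"
    )
    return GpsVector(scores=scores, n_snps_used=len(matrix.snps))


# ---------------------------------------------------------------------------
# File ingestion
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ("snp_id", "locus", "risk_allele", "other_allele", "source_trait")


def read_panel(path) -> SnpPanel:
    """Read a panel definition file (comma- or tab-separated, with header)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel file missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        proxy = row.get("proxy_r2")
        if proxy is not None and (pd.isna(proxy)):
            proxy = None
        weight = row.get("weight", 1.0)
        if weight is None or pd.isna(weight):
            weight = 1.0
        records.append(
            SnpRecord(
                snp_id=str(row["snp_id"]),
                locus=str(row["locus"]),
                risk_allele=str(row["risk_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                source_trait=str(row["source_trait"]),
                proxy_r2=None if proxy is None else float(proxy),
                weight=float(weight),
            )
        )
    return SnpPanel(records)


def read_genotype_csv(path, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Read a risk-allele-count CSV (rows=individuals, columns=snp_ids)."""
    df = pd.read_csv(path, index_col=0)
    if panel is not None:
        unknown = [c for c in df.columns if c not in panel]
        if unknown:
            raise SchemaError(f"genotype columns not in panel: {unknown}")
    try:
        return GenotypeMatrix(df)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _orient(dosage: pd.Series, counted: str, record: SnpRecord) -> pd.Series:
    """Re-express a counted-allele dosage as a risk-allele count.

    External sources (VCF, PLINK) carry no reliable strand declaration.  For
    an ambiguous (A/T or C/G) SNP a strand flip relabels risk <-> other
    allele, so a counted allele equal to the panel's *other* allele is
    indistinguishable from a flipped risk-allele count; rather than guess,
    that case is a hard :class:`StrandError`.  Non-ambiguous SNPs are safely
    resolvable: direct matches orient by label, complement matches are
    recognised strand flips and oriented accordingly.
    """
    counted = counted.upper()
    if counted == record.risk_allele:
        return dosage
    if counted == record.other_allele:
        if record.is_ambiguous:
            raise StrandError(
                f"{record.snp_id}: counted allele {counted} would need the "
                "panel's other-allele orientation, which for an ambiguous "
                "A/T or C/G SNP cannot be told apart from a strand flip"
            )
        return 2.0 - dosage
    comp = _COMPLEMENT.get(counted)
    if comp in (record.risk_allele, record.other_allele):
        return dosage if comp == record.risk_allele else 2.0 - dosage
    raise SchemaError(
        f"{record.snp_id}: counted allele {counted} matches neither panel allele"
    )


def read_plink_raw(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` (.raw) dosage table, oriented to risk alleles.

    Column headers are ``<snp_id>_<counted_allele>``; dosages count the
    declared allele and are flipped when it is the panel's other allele.
    Strand flips of ambiguous SNPs raise :class:`StrandError`.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in meta_cols:
        raise SchemaError("PLINK .raw file must contain an IID column")
    out = {}
    for col in df.columns:
        if col in meta_cols:
            continue
        if "_" not in col:
            raise SchemaError(f"{col!r} is not a <snp>_<allele> dosage column")
        snp_id, counted = col.rsplit("_", 1)
        if snp_id not in panel:
            continue
        out[snp_id] = _orient(df[col].astype(float), counted, panel[snp_id])
    matrix = pd.DataFrame(out)
    matrix.index = pd.Index(df["IID"].astype(str), name="id")
    return GenotypeMatrix(matrix)


def read_vcf(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read panel SNPs from a VCF (GT fields), oriented to risk alleles.

    Requires :mod:`cyvcf2` (optional dependency).  ALT-allele dosages are
    flipped when the panel's risk allele is REF; matches through strand
    complement follow the same rules as the PLINK reader.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, pd.Series] = {}
    for variant in vcf:
        snp_id = variant.ID
        if snp_id is None or snp_id not in panel:
            continue
        if len(variant.ALT) != 1:
            raise SchemaError(f"{snp_id}: expected a biallelic site")
        alt_counts = []
        for gt in variant.genotypes:
            alleles = [a for a in gt[:-1] if a != -1]
            alt_counts.append(float(sum(alleles)) if alleles else np.nan)
        dosage = pd.Series(alt_counts, index=samples, dtype=float)
        columns[snp_id] = _orient(dosage, variant.ALT[0], panel[snp_id])
    matrix = pd.DataFrame(columns)
    matrix.index = pd.Index(samples, name="id")
    return GenotypeMatrix(matrix)
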