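"""Structured analysis configuration.

One YAML document drives the whole pipeline: the SNP panel location, QC
thresholds, trait-derivation unit conventions, the variable ordering
(boxes), the clinically relevant interaction candidates, the selection and
edge-display significance levels, and prediction queries.  The default
configuration encodes the standard ordering for a two-arm lifestyle trial:

    outcomes | d_weight | d_satfat_pct, d_steps_k | arm | age, sex, country, gps

with outcomes the four glycaemic log-ratios, each analysed separately.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .chaingraph import Box, Variable, VariableOrdering
from .errors import ConfigurationError

__all__ = [
    "DEFAULT_CONFIG",
    "default_config",
    "load_config",
    "save_config",
    "ordering_from_config",
    "interaction_candidates_from_config",
]

OUTCOME_VARS = ("d_log_homa_ir", "d_log_homa_b", "d_log_glucose", "d_log_hba1c")

#: clinically relevant interaction candidates screened for every outcome:
#: genetic predisposition x weight loss, weight loss x diet quality, and
#: treatment arm x each lifestyle change.
_OUTCOME_CANDIDATES = [
    ["gps", "d_weight"],
    ["d_weight", "d_satfat_pct"],
    ["arm", "d_weight"],
    ["arm", "d_satfat_pct"],
]

DEFAULT_CONFIG: dict = {
    "qc": {
        "call_rate_threshold": 0.95,
        "max_failed_snps": 3,
        "hwe_alpha": 0.05,
        # number of Bonferroni tests; null = current panel size
        "hwe_tests": None,
    },
    "traits": {
        "insulin_conversion": 6.0,
        "calibration_ir": 1.0,
        "calibration_b": 1.0,
        "fat_energy_density": 37.0,
        "energy_unit": "kJ",
        "min_days_steps": 4,
    },
    "alphas": {"selection": 0.05, "edge": 0.10},
    "ordering": {
        "boxes": [
            {"variables": list(OUTCOME_VARS), "stacked": True},
            {"variables": ["d_weight"]},
            {"variables": ["d_satfat_pct", "d_steps_k"], "stacked": True},
            {"variables": ["arm"]},
            {"variables": ["age", "sex", "country", "gps"]},
        ],
        "variables": {
            "d_log_homa_ir": {"type": "continuous", "role": "response"},
            "d_log_homa_b": {"type": "continuous", "role": "response"},
            "d_log_glucose": {"type": "continuous", "role": "response"},
            "d_log_hba1c": {"type": "continuous", "role": "response"},
            "d_weight": {"type": "continuous", "role": "intermediate"},
            "d_satfat_pct": {"type": "continuous", "role": "intermediate"},
            "d_steps_k": {"type": "continuous", "role": "intermediate"},
            "arm": {"type": "categorical", "reference": "SC", "role": "treatment"},
            "age": {"type": "continuous", "role": "intrinsic"},
            "sex": {"type": "categorical", "reference": "female", "role": "intrinsic"},
            "country": {"type": "categorical", "reference": "UK", "role": "intrinsic"},
            "gps": {"type": "continuous", "role": "intrinsic"},
        },
    },
    "interactions": {outcome: copy.deepcopy(_OUTCOME_CANDIDATES) for outcome in OUTCOME_VARS},
    "predictions": [
        {
            "target": "d_log_homa_ir",
            "vary": "gps",
            "at": ["lower_quartile", "upper_quartile"],
        },
        {
            "target": "d_log_glucose",
            "vary": "gps",
            "at": ["lower_quartile", "upper_quartile"],
        },
    ],
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    """Load a YAML config, overlaying it on the defaults (shallow per section)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    cfg = default_config()
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def ordering_from_config(cfg: dict) -> VariableOrdering:
    section = cfg["ordering"]
    boxes = [
        Box(variables=tuple(b["variables"]), stacked=bool(b.get("stacked", False)))
        for b in section["boxes"]
    ]
    variables = {}
    for name, meta in section.get("variables", {}).items():
        variables[name] = Variable(
            name=name,
            vtype=meta.get("type", "continuous"),
            reference=meta.get("reference"),
            role=meta.get("role", "intermediate"),
        )
    return VariableOrdering(boxes, variables)


def interaction_candidates_from_config(cfg: dict) -> dict[str, list[tuple[str, str]]]:
    out = {}
    for response, pairs in cfg.get("interactions", {}).items():
        out[response] = [tuple(p) for p in pairs]
    return out
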