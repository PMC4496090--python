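"""Derivation of analysis variables from raw participant measurements.

Raw inputs are baseline ("_0") and 12-month ("_12") measurements of weight,
fasting glucose (mmol/L), fasting insulin (pmol/L), HbA1c (mmol/mol), daily
steps, dietary energy and saturated fat.  The analysis variables are:

* HOMA-IR and HOMA-B insulin sensitivity/secretion indices (closed-form
  HOMA1 with calibration hooks; precomputed columns, e.g. from the HOMA2
  computer model, are used verbatim when supplied),
* change scores: weight (kg), saturated fat (% of energy), steps (thousands
  per day), and
* log-ratio outcomes ln(month-12 / baseline) for HOMA-IR, HOMA-B, glucose
  and HbA1c, so that 0 means no change and the exponential is the
  final/baseline ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "KJ_PER_KCAL",
    "FAT_KJ_PER_G",
    "INSULIN_PMOL_PER_UU",
    "HOMA_B_GLUCOSE_FLOOR",
    "homa_indices",
    "log_change_ratio",
    "satfat_pct_energy",
    "nsp_from_aoac",
    "mean_daily_steps",
    "hba1c_percent_to_mmol_mol",
    "derive_changes",
]

KJ_PER_KCAL = 4.184
#: energy density of fat, kJ per gram (9 kcal/g)
FAT_KJ_PER_G = 37.0
#: insulin unit conversion, pmol/L per uU/mL (HOMA-calculator convention)
INSULIN_PMOL_PER_UU = 6.0
#: HOMA-B is undefined at or below this fasting glucose (mmol/L)
HOMA_B_GLUCOSE_FLOOR = 3.5

OUTCOMES = ("homa_ir", "homa_b", "glucose", "hba1c")


def homa_indices(
    glucose,
    insulin,
    insulin_conversion: float = INSULIN_PMOL_PER_UU,
    calibration: tuple[float, float] = (1.0, 1.0),
):
    """Closed-form HOMA1 insulin-resistance and beta-cell indices.

    Parameters
    ----------
    glucose : fasting plasma glucose, mmol/L (scalar or array)
    insulin : fasting insulin, pmol/L
    insulin_conversion : divisor taking pmol/L to uU/mL (default 6.0)
    calibration : multiplicative factors (ir, b) applied to each index,
        a hook for rescaling the closed-form HOMA1 output towards the
        HOMA2 computer model (default 1.0, i.e. plain HOMA1).

    Returns
    -------
    (homa_ir, homa_b) where ``homa_ir = cal_ir * G * I_uU / 22.5`` and
    ``homa_b = cal_b * 20 * I_uU / (G - 3.5)`` in percent.  HOMA-B is NaN
    wherever glucose <= 3.5 mmol/L (undefined-index flag); such records are
    retained, not dropped.
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g[np.isfinite(g)] <= 0):
        raise DomainError("glucose must be positive")
    if np.any(i[np.isfinite(i)] <= 0):
        raise DomainError("insulin must be positive")
    if insulin_conversion <= 0:
        raise DomainError("insulin_conversion must be positive")
    cal_ir, cal_b = calibration
    i_uu = i / insulin_conversion
    homa_ir = cal_ir * g * i_uu / 22.5
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_b = np.where(
            g > HOMA_B_GLUCOSE_FLOOR,
            cal_b * 20.0 * i_uu / (g - HOMA_B_GLUCOSE_FLOOR),
            np.nan,
        )
    if np.isscalar(glucose) and np.isscalar(insulin):
        return float(homa_ir), float(homa_b)
    return homa_ir, homa_b


def log_change_ratio(baseline, final):
    """ln(final / baseline); 0 iff no change, sign follows the direction."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(final, dtype=float)
    if np.any(b[np.isfinite(b)] <= 0) or np.any(f[np.isfinite(f)] <= 0):
        raise DomainError("log change ratio requires positive values")
    out = np.log(f) - np.log(b)
    if np.isscalar(baseline) and np.isscalar(final):
        return float(out)
    return out


def satfat_pct_energy(satfat_g, energy_kj, fat_energy_density: float = FAT_KJ_PER_G):
    """Percent of total energy contributed by saturated fat.

    ``100 * satfat_g * fat_energy_density / energy_kj``; energy must be in
    the same units as ``fat_energy_density`` implies (kJ by default, kcal if
    the density is given in kcal/g).
    """
    s = np.asarray(satfat_g, dtype=float)
    e = np.asarray(energy_kj, dtype=float)
    if np.any(e[np.isfinite(e)] <= 0):
        raise DomainError("energy must be positive")
    if np.any(s[np.isfinite(s)] < 0):
        raise DomainError("saturated fat intake cannot be negative")
    out = 100.0 * s * fat_energy_density / e
    if np.isscalar(satfat_g) and np.isscalar(energy_kj):
        return float(out)
    return out


def nsp_from_aoac(aoac_fibre_g):
    """Non-starch polysaccharide estimate: 0.75 x AOAC fibre (g/day)."""
    a = np.asarray(aoac_fibre_g, dtype=float)
    if np.any(a[np.isfinite(a)] < 0):
        raise DomainError("fibre intake cannot be negative")
    out = 0.75 * a
    return float(out) if np.isscalar(aoac_fibre_g) else out


def mean_daily_steps(step_counts, min_days: int = 4):
    """Average a 7-day pedometer diary.

    Returns the arithmetic mean of the non-missing daily counts, or NaN when
    fewer than ``min_days`` days were recorded (missing-activity flag).
    """
    counts = np.asarray(step_counts, dtype=float)
    observed = counts[np.isfinite(counts)]
    if observed.size < min_days:
        return float("nan")
    return float(observed.mean())


def hba1c_percent_to_mmol_mol(pct):
    """NGSP % to IFCC mmol/mol (linear map), for ingestion only."""
    p = np.asarray(pct, dtype=float)
    out = 10.929 * (p - 2.15)
    return float(out) if np.isscalar(pct) else out


_REQUIRED = [
    "weight_0", "weight_12",
    "glucose_0", "glucose_12",
    "insulin_0", "insulin_12",
    "hba1c_0", "hba1c_12",
    "steps_0", "steps_12",
    "energy_0", "energy_12",
    "satfat_g_0", "satfat_g_12",
]

_PASSTHROUGH = ["age", "sex", "country", "arm"]


@dataclass
class DerivedTable:
    """Per-participant analysis variables plus the exclusion log."""

    data: pd.DataFrame
    exclusions: pd.DataFrame

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")


def derive_changes(
    pheno: pd.DataFrame,
    *,
    insulin_conversion: float = INSULIN_PMOL_PER_UU,
    calibration: tuple[float, float] = (1.0, 1.0),
    fat_energy_density: float = FAT_KJ_PER_G,
    energy_unit: str = "kJ",
) -> DerivedTable:
    """Derive change scores and log-ratio outcomes for a phenotype table.

    ``pheno`` is indexed by participant id and follows the documented column
    schema (``*_0`` baseline, ``*_12`` month 12).  Rows missing any required
    measurement are excluded with a logged reason (complete-case contract);
    an undefined HOMA-B (glucose <= 3.5 at either time) leaves that single
    outcome missing but retains the record.  Saturated fat is converted to
    percent of energy; HOMA columns (``homa_ir_*``, ``homa_b_*``) are used
    when supplied and otherwise computed as closed-form HOMA1.
    """
    if energy_unit not in ("kJ", "kcal"):
        raise SchemaError("energy_unit must be 'kJ' or 'kcal'")
    missing_cols = [c for c in _REQUIRED if c not in pheno.columns]
    if missing_cols:
        raise SchemaError(f"phenotype table missing columns {missing_cols}")

    required = pheno[_REQUIRED]
    complete = required.notna().all(axis=1)
    reasons = required.isna().idxmax(axis=1)
    exclusions = pd.DataFrame(
        {
            "id": pheno.index[~complete],
            "reason": [f"missing {r}" for r in reasons[~complete]],
        }
    )
    df = pheno[complete].copy()

    energy_scale = KJ_PER_KCAL if energy_unit == "kcal" else 1.0
    energy_0 = df["energy_0"].to_numpy() * energy_scale
    energy_12 = df["energy_12"].to_numpy() * energy_scale

    out = pd.DataFrame(index=df.index)
    for col in _PASSTHROUGH:
        if col in df.columns:
            out[col] = df[col]

    satfat_pct_0 = satfat_pct_energy(df["satfat_g_0"], energy_0, fat_energy_density)
    satfat_pct_12 = satfat_pct_energy(df["satfat_g_12"], energy_12, fat_energy_density)
    out["satfat_pct_0"] = satfat_pct_0
    out["satfat_pct_12"] = satfat_pct_12

    # HOMA indices: precomputed columns win, closed-form HOMA1 otherwise.
    homa = {}
    for when in ("0", "12"):
        ir_col, b_col = f"homa_ir_{when}", f"homa_b_{when}"
        ir = df[ir_col] if ir_col in df.columns else None
        b = df[b_col] if b_col in df.columns else None
        if ir is None or b is None:
            ir_calc, b_calc = homa_indices(
                df[f"glucose_{when}"].to_numpy(),
                df[f"insulin_{when}"].to_numpy(),
                insulin_conversion,
                calibration,
            )
            ir = ir_calc if ir is None else ir
            b = b_calc if b is None else b
        homa[ir_col] = np.asarray(ir, dtype=float)
        homa[b_col] = np.asarray(b, dtype=float)
        out[ir_col] = homa[ir_col]
        out[b_col] = homa[b_col]

    out["d_weight"] = df["weight_12"] - df["weight_0"]
    out["d_steps_k"] = (df["steps_12"] - df["steps_0"]) / 1000.0
    out["d_satfat_pct"] = satfat_pct_12 - satfat_pct_0

    pairs = {
        "d_log_homa_ir": (homa["homa_ir_0"], homa["homa_ir_12"]),
        "d_log_homa_b": (homa["homa_b_0"], homa["homa_b_12"]),
        "d_log_glucose": (df["glucose_0"].to_numpy(), df["glucose_12"].to_numpy()),
        "d_log_hba1c": (df["hba1c_0"].to_numpy(), df["hba1c_12"].to_numpy()),
    }
    for name, (b0, b12) in pairs.items():
        valid = np.isfinite(b0) & np.isfinite(b12)
        vals = np.full(len(df), np.nan)
        vals[valid] = log_change_ratio(b0[valid], b12[valid])
        out[name] = vals

    if "aoac_fibre_g_0" in df.columns:
        out["nsp_g_0"] = nsp_from_aoac(df["aoac_fibre_g_0"].to_numpy())
    if "aoac_fibre_g_12" in df.columns:
        out["nsp_g_12"] = nsp_from_aoac(df["aoac_fibre_g_12"].to_numpy())
    if "gps" in df.columns:
        out["gps"] = df["gps"]

    return DerivedTable(data=out, exclusions=exclusions)
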