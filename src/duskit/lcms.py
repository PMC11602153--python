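"""Relative dihydrouridine quantification from nucleoside peak-area tables.

The within-sample normaliser is the adenosine UV (254 nm) peak area, which is
stable and free of co-elution artefacts; the D mass-spectrometric signal of a
sample is divided by its adenosine UV signal and then expressed as percent of
the same ratio in a control sample (control = 100%).  This makes the measure
invariant to injection amount.  The module also provides:

* replicate statistics with a pooled-variance two-sample Student's t-test
  (Welch available behind a flag),
* knockout decomposition: each enzyme's contribution to total D from the
  fractional decrease of its single-knockout strain,
* an MRM transition calculator from molecular formulas (monoisotopic masses,
  +1 protonation; nucleosides typically lose the ribose, -132 u),
* external-standard linear calibration and fold-change for NADPH.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Monoisotopic element masses, u (CODATA/IUPAC 2021 values).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

#: Mass of the proton, u.
PROTON_MASS = 1.007276467

#: Convenience formulas for the analytes monitored in this package.
FORMULAS = {
    "dihydrouridine": "C9H14N2O6",
    "ribose_loss": "C5H8O4",
    "NADPH": "C21H30N7O17P3",
    "NH3": "NH3",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map over {C, H, N, O, P}."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element, num = match.group(1), match.group(2)
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {element!r} in {formula!r}")
            counts[element] = counts.get(element, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts=tuple(sorted(counts.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def monoisotopic_mass(self) -> float:
        return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in self.counts))


@dataclass(frozen=True)
class MzTransition:
    precursor_mz: float
    product_mz: float
    precursor_nominal: int
    product_nominal: int


def mz_transition(
    formula: MolecularFormula | str,
    neutral_loss: MolecularFormula | str | None = None,
) -> MzTransition:
    """Precursor and product m/z for a protonated, singly charged analyte.

    precursor = monoisotopic(formula) + proton; product = precursor -
    monoisotopic(neutral_loss).  Nominal values are the monoisotopic m/z
    rounded to the nearest integer, matching how triple-quadrupole
    transitions are usually quoted (e.g. dihydrouridine 247 -> 115 by ribose
    loss; NADPH 746 -> 729 by NH3 loss).
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    if neutral_loss is None:
        loss = MolecularFormula(counts=())
    elif isinstance(neutral_loss, str):
        loss = MolecularFormula.parse(neutral_loss) if neutral_loss else MolecularFormula(counts=())
    else:
        loss = neutral_loss
    parent = formula.as_dict()
    for element, n in loss.counts:
        if parent.get(element, 0) < n:
            raise ValueError(f"neutral loss exceeds formula for element {element}")
    precursor = formula.monoisotopic_mass() + PROTON_MASS
    product = precursor - loss.monoisotopic_mass()
    return MzTransition(
        precursor_mz=precursor,
        product_mz=product,
        precursor_nominal=int(round(precursor)),
        product_nominal=int(round(product)),
    )


# ---------------------------------------------------------------------------
# relative quantification
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    mean: float
    sd: float
    n: int
    p_value: float | None
    significance: str
    flag: str = ""


@dataclass
class RelativeLevel:
    """Relative D level of a sample group, control = 100%."""

    sample: str
    values: list[float]
    control_values: list[float]
    mean: float
    sd: float
    n: int
    p_value: float | None
    significance: str
    flag: str = ""


def significance_label(p_value: float | None) -> str:
    """Star convention: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if p_value is None or np.isnan(p_value):
        return "na"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def _dm_over_auv(table: pd.DataFrame, sample: str) -> float:
    rows = table[table["sample"] == sample]
    d = rows[(rows["analyte"] == "D") & (rows["channel"] == "MS")]
    a = rows[(rows["analyte"] == "A") & (rows["channel"] == "UV254")]
    if d.empty or a.empty:
        raise ValueError(f"sample {sample!r} lacks a (D, MS) or (A, UV254) row")
    a_area = float(a["area"].iloc[0])
    if a_area == 0:
        raise ValueError(f"sample {sample!r} has zero adenosine UV area")
    return float(d["area"].iloc[0]) / a_area


def relative_d_level(
    sample_rows: pd.DataFrame,
    control_rows: pd.DataFrame,
    sample_name: str | None = None,
    welch: bool = False,
) -> RelativeLevel:
    """Relative D level: 100 x (D_MS/A_UV)_sample / mean (D_MS/A_UV)_control.

    Both tables may contain several replicate samples (distinct ``sample``
    values); the control normaliser is the mean control ratio, and per-
    replicate sample values feed the summary statistics and the t-test
    against the control replicates (themselves expressed on the same scale).
    """
    sample_ids = list(dict.fromkeys(sample_rows["sample"]))
    control_ids = list(dict.fromkeys(control_rows["sample"]))
    if not sample_ids or not control_ids:
        raise ValueError("empty sample or control table")
    control_ratios = [_dm_over_auv(control_rows, s) for s in control_ids]
    control_mean = float(np.mean(control_ratios))
    if control_mean == 0:
        raise ValueError("control D/A ratio is zero")
    values = [100.0 * _dm_over_auv(sample_rows, s) / control_mean for s in sample_ids]
    control_values = [100.0 * r / control_mean for r in control_ratios]
    summary = summarize_replicates(values, control_values, welch=welch)
    return RelativeLevel(
        sample=sample_name or sample_ids[0],
        values=values,
        control_values=control_values,
        mean=summary.mean,
        sd=summary.sd,
        n=summary.n,
        p_value=summary.p_value,
        significance=summary.significance,
        flag=summary.flag,
    )


def summarize_replicates(
    group: list[float] | np.ndarray,
    control: list[float] | np.ndarray,
    welch: bool = False,
) -> ReplicateSummary:
    """Mean, SD and a two-tailed two-sample Student's t-test vs the control.

    The default is the classical pooled-variance test (the field's customary
    choice); Welch's unequal-variance variant is available via ``welch``.
    Groups with fewer than two replicates on either side return statistics
    without a p-value, flagged ``insufficient_replicates``.
    """
    group = np.asarray(group, dtype=float)
    control = np.asarray(control, dtype=float)
    mean = float(group.mean())
    sd = float(group.std(ddof=1)) if group.size > 1 else 0.0
    if group.size < 2 or control.size < 2:
        return ReplicateSummary(
            mean=mean, sd=sd, n=int(group.size), p_value=None,
            significance="na", flag="insufficient_replicates",
        )
    result = stats.ttest_ind(group, control, equal_var=not welch)
    p = float(result.pvalue)
    if np.isnan(p):  # zero pooled variance with equal means
        p = 1.0 if np.isclose(mean, control.mean()) else 0.0
    return ReplicateSummary(
        mean=mean, sd=sd, n=int(group.size), p_value=p,
        significance=significance_label(p),
    )


def relative_levels_table(levels: list[RelativeLevel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": lv.sample,
                "relative_percent": lv.mean,
                "mean": lv.mean,
                "sd": lv.sd,
                "n": lv.n,
                "p_value": lv.p_value if lv.p_value is not None else float("nan"),
                "significance_label": lv.significance,
            }
            for lv in levels
        ],
        columns=["sample", "relative_percent", "mean", "sd", "n", "p_value", "significance_label"],
    )


# ---------------------------------------------------------------------------
# knockout decomposition, calibration, fold change
# ---------------------------------------------------------------------------


@dataclass
class Decomposition:
    contributions: dict[str, float]
    residual: float


def decompose_contributions(
    wt_level: float, knockout_levels: dict[str, float]
) -> Decomposition:
    """Each enzyme's share of total D from its single-knockout decrease.

    contribution(E) = 100 x (1 - level(deltaE) / level(WT)); the closure
    residual 100 - sum(contributions) is reported, not hidden — a nonzero
    residual leaves room for sites modified by more than one enzyme or for
    measurement noise.
    """
    if wt_level == 0:
        raise ValueError("wild-type level must be nonzero")
    contributions = {
        enzyme: 100.0 * (1.0 - level / wt_level)
        for enzyme, level in knockout_levels.items()
    }
    residual = 100.0 - sum(contributions.values())
    return Decomposition(contributions=contributions, residual=residual)


@dataclass
class Calibration:
    slope: float
    intercept: float
    r_value: float

    def quantify(self, areas) -> tuple[np.ndarray, np.ndarray]:
        """Concentrations for sample areas; negatives clamped to 0 + flag."""
        areas = np.asarray(areas, dtype=float)
        conc = (areas - self.intercept) / self.slope
        clamped = conc < -1e-12  # genuinely negative, not rounding error
        return np.where(conc < 0, 0.0, conc), clamped


def calibrate_and_quantify(
    standards: list[tuple[float, float]], sample_areas
) -> tuple[np.ndarray, np.ndarray, Calibration]:
    """External calibration: OLS line area = a x conc + b, then invert.

    Requires at least two distinct standard concentrations.  Returns
    (concentrations, clamped flags, calibration).
    """
    conc = np.asarray([s[0] for s in standards], dtype=float)
    area = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need at least two distinct standard concentrations")
    fit = stats.linregress(conc, area)
    calibration = Calibration(
        slope=float(fit.slope), intercept=float(fit.intercept), r_value=float(fit.rvalue)
    )
    values, clamped = calibration.quantify(sample_areas)
    return values, clamped, calibration


@dataclass
class FoldChange:
    value: float | None
    censored: bool = False
    label: str = ""


def fold_change(
    control_conc: float, treated_conc: float, limit_of_detection: float | None = None
) -> FoldChange:
    """Fold drop control/treated; a zero treated value is reported as a
    censored bound (>= control / limit-of-detection) rather than infinity."""
    if treated_conc > 0:
        return FoldChange(value=control_conc / treated_conc)
    if limit_of_detection and limit_of_detection > 0:
        bound = control_conc / limit_of_detection
        return FoldChange(value=bound, censored=True, label=f">= {bound:.3g}")
    return FoldChange(value=None, censored=True, label="treated below detection")
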