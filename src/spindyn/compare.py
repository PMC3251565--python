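"""Wild-type vs mutant dynamics comparison.

Builds per-residue comparison rows (percent differences, fold changes,
internal-timescale bands) from two sets of relaxation/model-free
results, plus composite amide chemical-shift perturbation screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd

#: Quantities compared between the two proteins, in report order.
QUANTITIES = ("R1", "R2", "NOE", "S2", "te", "rex")

#: τe band edges (s): above 500 ps is slow, 50-500 ps intermediate.
TAU_E_SLOW_S = 500e-12
TAU_E_FAST_S = 50e-12


@dataclass(frozen=True)
class ResidueComparison:
    """One residue/quantity pair compared between proteins A and B."""

    residue_id: int
    quantity: str
    value_a: float
    value_b: float
    pct_higher_a_over_b: float
    pct_lower_b_under_a: float
    fold_ratio: float
    missing: bool = False


def percent_higher(a: float, b: float) -> float:
    """How much higher a is than b, as 100 (a - b)/b."""
    if b <= 0:
        raise ValueError("reference value b must be positive")
    return 100.0 * (a - b) / b


def percent_lower(a: float, b: float) -> float:
    """How much lower b is than the reference a, as 100 (a - b)/a."""
    if a <= 0:
        raise ValueError("reference value a must be positive")
    return 100.0 * (a - b) / a


def fold_ratio(a: float, b: float) -> float:
    """Symmetric fold change max(a, b)/min(a, b) >= 1."""
    if a <= 0 or b <= 0:
        raise ValueError("fold ratio requires positive values")
    return max(a, b) / min(a, b)


def classify_tau_e(te_s: float) -> str:
    """Band the internal correlation time: slow / intermediate / fast.

    slow for τe > 500 ps, intermediate for 50 ps < τe <= 500 ps, fast
    for τe <= 50 ps (boundaries belong to the slower-numbered band).
    """
    if te_s < 0:
        raise ValueError("te must be >= 0")
    if te_s > TAU_E_SLOW_S:
        return "slow"
    if te_s > TAU_E_FAST_S:
        return "intermediate"
    return "fast"


def composite_shift_difference(d_h: float, d_n: float, n_weight: float = 5.0) -> float:
    """Composite amide chemical-shift difference in ppm.

    The standard amide weighting sqrt(ΔδH² + (ΔδN/w)²) with w = 5 by
    default, reflecting the relative ¹⁵N shift dispersion.
    """
    if not (math.isfinite(d_h) and math.isfinite(d_n)):
        raise ValueError("shift differences must be finite")
    return math.sqrt(d_h**2 + (d_n / n_weight) ** 2)


def flag_shift_perturbations(
    shifts: pd.DataFrame, threshold: float = 0.3, n_weight: float = 5.0
) -> pd.DataFrame:
    """Composite shifts with a perturbation flag above ``threshold`` ppm.

    ``shifts`` needs columns residue, dH_ppm, dN_ppm.
    """
    out = shifts.copy()
    out["composite_ppm"] = [
        composite_shift_difference(h, n, n_weight)
        for h, n in zip(out["dH_ppm"], out["dN_ppm"])
    ]
    out["perturbed"] = out["composite_ppm"] > threshold
    return out


def _compare_pair(residue_id: int, quantity: str, a: float, b: float) -> ResidueComparison:
    valid = (
        a is not None and b is not None
        and np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0
    )
    if not valid:
        return ResidueComparison(
            residue_id=residue_id, quantity=quantity,
            value_a=a if a is not None else np.nan,
            value_b=b if b is not None else np.nan,
            pct_higher_a_over_b=np.nan, pct_lower_b_under_a=np.nan,
            fold_ratio=np.nan, missing=True,
        )
    return ResidueComparison(
        residue_id=residue_id,
        quantity=quantity,
        value_a=a,
        value_b=b,
        pct_higher_a_over_b=percent_higher(a, b),
        pct_lower_b_under_a=percent_lower(a, b),
        fold_ratio=fold_ratio(a, b),
    )


def build_comparison_table(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Per-residue, per-quantity comparison of two result tables.

    Each input holds one row per residue, indexed by a ``residue``
    column, with any subset of the columns R1, R2, NOE, S2, te_ns, rex.
    Residues present in only one table appear flagged as missing; an
    empty residue overlap (nothing to compare at all) is an error.
    A is the reference protein for the percent-lower direction.
    """
    a = results_a.set_index("residue")
    b = results_b.set_index("residue")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared residues between the two result sets")
    all_ids = a.index.union(b.index).sort_values()
    rows = []
    for residue in all_ids:
        for quantity in QUANTITIES:
            col = "te_ns" if quantity == "te" else quantity
            va = a[col].get(residue, np.nan) if col in a else np.nan
            vb = b[col].get(residue, np.nan) if col in b else np.nan
            rows.append(_compare_pair(int(residue), quantity, va, vb))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame


def render_report(comparison: pd.DataFrame, label_a: str = "A", label_b: str = "B") -> str:
    """Human-readable markdown report of a comparison table.

    Percent differences are rounded to integers and fold changes to one
    decimal, the conventional precision of such tables; the machine
    output (the comparison table itself) keeps full precision.
    Deterministic: identical inputs yield identical bytes.
    """
    lines = [
        f"# Dynamics comparison: {label_a} vs {label_b}",
        "",
        f"| residue | quantity | {label_a} | {label_b} | % higher ({label_a}/{label_b}) | % lower ({label_b} vs {label_a}) | fold |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in comparison.itertuples():
        if row.missing:
            lines.append(
                f"| {row.residue_id} | {row.quantity} | - | - | missing | missing | - |"
            )
        else:
            lines.append(
                f"| {row.residue_id} | {row.quantity} | {row.value_a:.4g} | {row.value_b:.4g} "
                f"| {row.pct_higher_a_over_b:.0f}% | {row.pct_lower_b_under_a:.0f}% "
                f"| {row.fold_ratio:.1f} |"
            )
    return "\n".join(lines) + "\n"
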