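"""Plasticity classification and the SOC (sum of change) statistic.

Differentially expressed genes are assigned a direction — increasing or
decreasing with temperature — or, for quadratic reaction norms whose end
temperatures differ by less than 80 % of the full fitted range, a U (upward
parabola) or bell (downward parabola) shape. Genes that are not
differential are conserved. The SOC accumulates absolute log2 fold changes
between consecutive temperatures no more than 6 °C apart; it is
scale-invariant and zero exactly for flat profiles. A signed-to-absolute
ratio is kept as a diagnostic of how consistently the changes point one way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .reaction_norm import ReactionNormFit

__all__ = [
    "CLASS_LABELS",
    "PlasticityProfile",
    "SocResult",
    "soc",
    "classify_direction",
    "build_profiles",
    "tabulate_classes",
]

CLASS_LABELS = ("conserved", "increasing", "decreasing", "U", "bell")
DEFAULT_OPEN_FRACTION = 0.80
DEFAULT_MAX_GAP = 6.0


@dataclass
class PlasticityProfile:
    gene_id: str
    class_label: str
    curvature: str  # "none" | "linear" | "quadratic"
    soc: float
    soc_direction_ratio: float
    quadratic_coefficient: float  # NaN unless the quadratic model was selected


class SocResult(NamedTuple):
    soc: float
    direction_ratio: float


def soc(normalized_means, temperatures, max_gap: float = DEFAULT_MAX_GAP) -> SocResult:
    """Sum of change of one gene across the temperature gradient.

    ``SOC = Σ |log2 mean(T_{i+1}) − log2 mean(T_i)|`` over consecutive
    temperature pairs with gap ≤ ``max_gap`` °C. ``direction_ratio`` is the
    signed sum divided by the absolute sum (0 for a flat gene), in [−1, 1].
    """
    means = np.asarray(normalized_means, dtype=float)
    temps = np.asarray(temperatures, dtype=float)
    if means.shape != temps.shape:
        raise ValueError("means and temperatures must have equal length")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be sorted strictly increasing")
    if np.any(means <= 0):
        raise ValueError("normalized means must be positive")
    diffs = np.diff(np.log2(means))
    include = np.diff(temps) <= max_gap + 1e-12
    signed = diffs[include].sum()
    total = np.abs(diffs[include]).sum()
    ratio = signed / total if total > 0 else 0.0
    return SocResult(float(total), float(ratio))


def _classify_one(
    model: str,
    b1: float,
    b2: float,
    log2_fitted: np.ndarray,
    is_differential: bool,
    open_fraction: float,
) -> str:
    if not is_differential or model == "null":
        return "conserved"
    if model == "linear":
        return "increasing" if b1 > 0 else "decreasing"
    # quadratic: the 80% end-difference rule on log2 fitted means
    delta_end = abs(log2_fitted[-1] - log2_fitted[0])
    delta_range = log2_fitted.max() - log2_fitted.min()
    if delta_end < open_fraction * delta_range:
        return "U" if b2 > 0 else "bell"
    return "increasing" if log2_fitted[-1] > log2_fitted[0] else "decreasing"


def classify_direction(
    fit: ReactionNormFit,
    is_differential: bool,
    open_fraction: float = DEFAULT_OPEN_FRACTION,
) -> str:
    """Class label of a single fitted gene (see module docstring for rules)."""
    temps = sorted(fit.fitted_means)
    fitted = np.array([fit.fitted_means[t] for t in temps], dtype=float)
    if np.any(fitted <= 0):
        raise ValueError("fitted means must be positive")
    b1, b2 = fit.poly_coefficients[1], fit.poly_coefficients[2]
    return _classify_one(fit.model, b1, b2, np.log2(fitted), is_differential, open_fraction)


def build_profiles(
    fits: pd.DataFrame,
    normalized_counts: pd.DataFrame,
    temperatures,
    differential: pd.Series | None = None,
    open_fraction: float = DEFAULT_OPEN_FRACTION,
    max_gap: float = DEFAULT_MAX_GAP,
    average: str = "mean",
) -> pd.DataFrame:
    """Per-gene plasticity profiles from a fits table.

    SOC is computed on per-temperature averages (``mean`` or ``median``) of
    the TMM-normalized counts, not on fitted values. ``differential``
    defaults to the ``differential`` column of the fits table.
    """
    from .reaction_norm import call_differential_frame

    temps = np.asarray(temperatures, dtype=float)
    design_temps = np.unique(temps)
    if differential is None:
        differential = (
            fits["differential"]
            if "differential" in fits.columns
            else call_differential_frame(fits)
        )
    differential = differential.reindex(fits.index)

    cpm = normalized_counts.loc[fits.index].to_numpy(dtype=float)
    agg = np.median if average == "median" else np.mean
    if average not in ("mean", "median"):
        raise ValueError("average must be 'mean' or 'median'")
    temp_means = np.column_stack([agg(cpm[:, temps == t], axis=1) for t in design_temps])
    if np.any(temp_means <= 0):
        raise ValueError("per-temperature normalized means must be positive")

    include = np.diff(design_temps) <= max_gap + 1e-12
    log2m = np.log2(temp_means)
    diffs = np.diff(log2m, axis=1)[:, include]
    soc_vals = np.abs(diffs).sum(axis=1)
    signed = diffs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(soc_vals > 0, signed / soc_vals, 0.0)

    fitted_cols = [f"fitted_T{t:g}" for t in design_temps]
    log2_fitted = np.log2(fits[fitted_cols].to_numpy(dtype=float))
    labels = [
        _classify_one(
            fits["model"].iat[i],
            fits["b1"].iat[i],
            fits["b2"].iat[i],
            log2_fitted[i],
            bool(differential.iat[i]),
            open_fraction,
        )
        for i in range(len(fits))
    ]
    curvature = np.where(
        np.array(labels) == "conserved",
        "none",
        np.where(fits["model"] == "quadratic", "quadratic", "linear"),
    )
    quad_coef = np.where(fits["model"] == "quadratic", fits["b2"], np.nan)

    return pd.DataFrame(
        {
            "class_label": labels,
            "curvature": curvature,
            "soc": soc_vals,
            "soc_direction_ratio": ratio,
            "quadratic_coefficient": quad_coef,
        },
        index=fits.index.copy(),
    )


def tabulate_classes(profiles: pd.DataFrame) -> dict:
    """Class-count summary shaped like the direction × curvature table.

    Increasing/decreasing are split into linear and quadratic; the total
    always equals the number of genes (partition invariant).
    """
    table: dict = {"conserved": 0, "U": 0, "bell": 0}
    for direction in ("increasing", "decreasing"):
        table[direction] = {"linear": 0, "quadratic": 0, "total": 0}
    for label, curv in zip(profiles.get("class_label", []), profiles.get("curvature", [])):
        if label in ("increasing", "decreasing"):
            table[label][curv] += 1
            table[label]["total"] += 1
        else:
            table[label] += 1
    table["total"] = int(len(profiles))
    return table
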