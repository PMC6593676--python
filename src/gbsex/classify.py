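"""Sex classification from (H, P_Y) and evaluation against recorded sexes.

A sample is called male when its Y non-missingness clears a quadratic
boundary in the adjusted X heterozygosity,

    P_Y > c * H**2 + a        (defaults c = 20, a = 0.2)

and female when it falls below a linear one,

    P_Y < b + s * H           (defaults b = 0.1, s = 1),

with strict inequalities; points on a boundary, or between the two
regions, are left unassigned.  With the default coefficients the two
regions are disjoint for every H >= 0 (the gap polynomial
``20 H**2 - H + 0.1`` has negative discriminant), which is re-checked at
construction for any custom coefficients.

Evaluation distinguishes *concordance* — the fraction of samples whose
prediction matches the recorded sex, unassigned counting as discordant —
from accuracy/sensitivity/specificity, computed among assigned samples
against verified sexes (sensitivity: true female predicted female;
specificity: true male predicted male).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FEMALE, MALE, UNASSIGNED, UNKNOWN
from .errors import ConsistencyError

__all__ = [
    "DecisionBoundaries",
    "classify",
    "classify_many",
    "predict_cohort",
    "concordance",
    "accuracy_sensitivity_specificity",
    "gender_plot_data",
]


@dataclass(frozen=True)
class DecisionBoundaries:
    male_quad_coeff: float = 20.0
    male_intercept: float = 0.2
    female_slope: float = 1.0
    female_intercept: float = 0.1

    def __post_init__(self) -> None:
        # male region must sit strictly above the female region for H >= 0:
        # g(H) = male_quad*H^2 - female_slope*H + (male_int - female_int) >= 0
        a, s = self.male_quad_coeff, self.female_slope
        c0 = self.male_intercept - self.female_intercept
        if a > 0 and s > 0:
            h_star = s / (2 * a)
            g_min = c0 - s * s / (4 * a)
        elif s <= 0:
            h_star, g_min = 0.0, c0
        else:  # a <= 0 with positive slope: gap unbounded below
            h_star, g_min = float("inf"), float("-inf")
        if g_min < 0:
            raise ConsistencyError(
                f"male and female regions overlap (gap {g_min:.4g} at H={h_star:.4g})"
            )

    def male_curve(self, h):
        return self.male_quad_coeff * np.square(h) + self.male_intercept

    def female_line(self, h):
        return self.female_intercept + self.female_slope * np.asarray(h)


def classify(h: float, p_y: float, b: DecisionBoundaries | None = None) -> str:
    """Classify one sample: 'M', 'F' or 'U' (unassigned).

    Callers must not pass an undefined H; unusable samples are unassigned
    upstream in :func:`predict_cohort`.
    """
    b = b or DecisionBoundaries()
    if p_y > b.male_curve(h):
        return MALE
    if p_y < b.female_line(h):
        return FEMALE
    return UNASSIGNED


def classify_many(h: np.ndarray, p_y: np.ndarray, b: DecisionBoundaries | None = None) -> np.ndarray:
    b = b or DecisionBoundaries()
    h = np.asarray(h, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    out = np.full(h.shape, UNASSIGNED, dtype=object)
    with np.errstate(invalid="ignore"):
        out[p_y > b.male_curve(h)] = MALE
        out[p_y < b.female_line(h)] = FEMALE
    return out


def predict_cohort(
    stats: pd.DataFrame,
    genders: pd.Series | None = None,
    b: DecisionBoundaries | None = None,
) -> pd.DataFrame:
    """Classify every sample in a stats table and join recorded sexes.

    Unusable samples (low depth, zero denominator) are unassigned with
    their reason carried through; samples absent from ``genders`` get
    recorded sex 'U'.  Returns columns sample_id, predicted, recorded,
    concordant, reason.
    """
    b = b or DecisionBoundaries()
    if genders is not None and genders.index.duplicated().any():
        raise ConsistencyError("duplicated sample_id in gender table")
    if len(stats) == 0:
        return pd.DataFrame(columns=["sample_id", "predicted", "recorded", "concordant", "reason"])
    usable = stats["usable"].to_numpy(bool)
    predicted = np.full(len(stats), UNASSIGNED, dtype=object)
    predicted[usable] = classify_many(
        stats.loc[usable, "H"].to_numpy(), stats.loc[usable, "P_Y"].to_numpy(), b
    )
    if genders is None:
        recorded = np.full(len(stats), UNKNOWN, dtype=object)
    else:
        recorded = genders.reindex(stats["sample_id"]).fillna(UNKNOWN).to_numpy(dtype=object)
    concordant = (
        (predicted == recorded) & (predicted != UNASSIGNED) & (recorded != UNKNOWN)
    )
    return pd.DataFrame(
        {
            "sample_id": stats["sample_id"].to_numpy(),
            "predicted": predicted,
            "recorded": recorded,
            "concordant": concordant,
            "reason": stats["reasons"].to_numpy(),
        }
    )


def concordance(preds: pd.DataFrame) -> float:
    """Fraction of recorded-sex samples whose prediction matches the record.

    Unassigned predictions count as discordant.  NaN when no sample has a
    recorded sex.
    """
    known = preds["recorded"] != UNKNOWN
    n = int(known.sum())
    if n == 0:
        return float("nan")
    return float(preds.loc[known, "concordant"].sum() / n)


def accuracy_sensitivity_specificity(
    preds: pd.DataFrame, true_genders: pd.Series
) -> dict[str, float]:
    """Evaluate assigned predictions against verified sexes.

    Computed over samples with a prediction (not unassigned) and a known
    true sex.  Returns accuracy (overall agreement), sensitivity
    (P(predicted female | true female)) and specificity (P(predicted male |
    true male)), each NaN when its denominator is empty, plus the
    unassigned count for reporting.
    """
    truth = true_genders.reindex(preds["sample_id"]).to_numpy(dtype=object)
    predicted = preds["predicted"].to_numpy(dtype=object)
    assigned = (predicted != UNASSIGNED) & pd.notna(truth) & (truth != UNKNOWN)

    def _rate(num_mask, den_mask) -> float:
        den = int(den_mask.sum())
        return float(num_mask.sum() / den) if den else float("nan")

    truth_f = assigned & (truth == FEMALE)
    truth_m = assigned & (truth == MALE)
    return {
        "accuracy": _rate(assigned & (predicted == truth), assigned),
        "sensitivity": _rate(truth_f & (predicted == FEMALE), truth_f),
        "specificity": _rate(truth_m & (predicted == MALE), truth_m),
        "n_assigned": int(assigned.sum()),
        "n_unassigned": int((predicted == UNASSIGNED).sum()),
    }


def gender_plot_data(
    stats: pd.DataFrame,
    preds: pd.DataFrame,
    b: DecisionBoundaries | None = None,
    h_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinates for the sex-assignment scatter plot.

    Following the field's convention the y axis is the *count* of
    non-missing Y SNPs, ``M_y * P_Y``, against H on x.  Returns the
    per-sample point table and the two boundary curves sampled on
    ``h_grid`` (default: 201 points over [0, max(1, observed H))]).
    """
    b = b or DecisionBoundaries()
    if len(stats):
        m_y = int(stats["m_y"].iloc[0])
        h = stats["H"].to_numpy(float)
        points = pd.DataFrame(
            {
                "sample_id": stats["sample_id"].to_numpy(),
                "H": h,
                "y": m_y * stats["P_Y"].to_numpy(float),
                "predicted": preds.set_index("sample_id")["predicted"]
                .reindex(stats["sample_id"])
                .to_numpy(dtype=object),
                "recorded": preds.set_index("sample_id")["recorded"]
                .reindex(stats["sample_id"])
                .to_numpy(dtype=object),
            }
        )
        h_max = float(np.nanmax(h)) if np.isfinite(h).any() else 1.0
    else:
        m_y = 1
        points = pd.DataFrame(columns=["sample_id", "H", "y", "predicted", "recorded"])
        h_max = 1.0
    if h_grid is None:
        h_grid = np.linspace(0.0, max(1.0, h_max), 201)
    curves = pd.DataFrame(
        {
            "H": h_grid,
            "male_boundary_y": m_y * b.male_curve(h_grid),
            "female_boundary_y": m_y * b.female_line(h_grid),
        }
    )
    return points, curves
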