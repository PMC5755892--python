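"""Method-agreement statistics for paired automated/reference volumes.

Implements the validation toolkit used to compare an automated volumetry
against a reference standard: per-pair percent differences, ordinary
least-squares regression of automated (y) on reference (x), and
Bland–Altman bias with limits of agreement.  Each sinus is treated as an
independent observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QUANTITIES = ("total", "air_free")
_COLUMNS = ["exam_id", "side", "quantity", "automated_cm3", "reference_cm3"]


class AgreementInputError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float


class PairedVolumes:
    """Validated table of paired (automated, reference) volumes.

    One row per (exam, side, quantity); quantities are ``total`` and
    ``air_free`` (the air-containing volume after excluding involvement).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise AgreementInputError(f"missing columns: {missing}")
        frame = frame[_COLUMNS].copy()
        bad_q = set(frame["quantity"]) - set(QUANTITIES)
        if bad_q:
            raise AgreementInputError(f"unknown quantities {sorted(bad_q)}")
        if (frame["automated_cm3"] <= 0).any() or (frame["reference_cm3"] <= 0).any():
            raise AgreementInputError("all volumes must be positive")
        key = ["exam_id", "side", "quantity"]
        if frame.duplicated(subset=key).any():
            dups = frame[frame.duplicated(subset=key, keep=False)][key]
            raise AgreementInputError(f"duplicate (exam_id, side, quantity) rows:\n{dups}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "PairedVolumes":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def subset(self, quantity: str) -> pd.DataFrame:
        return self.frame[self.frame["quantity"] == quantity]

    def quantities(self) -> list[str]:
        return [q for q in QUANTITIES if (self.frame["quantity"] == q).any()]


def percent_difference(automated_cm3, reference_cm3):
    """Absolute percent difference, 100·|automated − reference| / reference."""
    a = np.asarray(automated_cm3, dtype=float)
    r = np.asarray(reference_cm3, dtype=float)
    if np.any(r <= 0):
        raise AgreementInputError("reference volumes must be positive")
    out = 100.0 * np.abs(a - r) / r
    return float(out) if out.ndim == 0 else out


def fit_regression(pairs: PairedVolumes, quantity: str) -> RegressionFit:
    """OLS of automated (y) on reference (x); R² is the squared Pearson r."""
    sub = pairs.subset(quantity)
    if len(sub) < 3:
        raise AgreementInputError(f"need >= 3 pairs for regression, got {len(sub)}")
    x = sub["reference_cm3"].to_numpy(float)
    y = sub["automated_cm3"].to_numpy(float)
    if np.ptp(x) == 0:
        raise AgreementInputError("reference volumes are constant; regression degenerate")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def bland_altman(
    pairs: PairedVolumes, quantity: str, loa_multiplier: float = 1.96
) -> BlandAltman:
    """Bias and limits of agreement of automated − reference differences.

    Limits are bias ± multiplier × sample SD (n−1) of the differences;
    the default multiplier 1.96 approximates a 95 % interval, 2.0 is the
    common round alternative.
    """
    sub = pairs.subset(quantity)
    if len(sub) < 3:
        raise AgreementInputError(f"need >= 3 pairs for Bland-Altman, got {len(sub)}")
    d = sub["automated_cm3"].to_numpy(float) - sub["reference_cm3"].to_numpy(float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        n=len(d),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
    )


def summarize_cohort(pairs: PairedVolumes, loa_multiplier: float = 1.96) -> dict:
    """Full agreement report per quantity, JSON-serialisable.

    Includes mean ± SD percent difference, regression, Bland–Altman, and the
    cohort mean ± SD of the automated total volumes.
    """
    quantities = pairs.quantities()
    if not quantities:
        raise AgreementInputError("no pairs for any known quantity")
    report: dict = {"quantities": {}}
    for q in quantities:
        sub = pairs.subset(q)
        pd_i = percent_difference(
            sub["automated_cm3"].to_numpy(float), sub["reference_cm3"].to_numpy(float)
        )
        reg = fit_regression(pairs, q)
        ba = bland_altman(pairs, q, loa_multiplier)
        report["quantities"][q] = {
            "n_pairs": int(len(sub)),
            "mean_percent_difference": float(np.mean(pd_i)),
            "sd_percent_difference": float(np.std(pd_i, ddof=1)) if len(pd_i) > 1 else 0.0,
            "regression": {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
            },
            "bland_altman": {
                "bias": ba.bias,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "loa_multiplier": ba.loa_multiplier,
            },
        }
    if "total" in quantities:
        tot = pairs.subset("total")["automated_cm3"].to_numpy(float)
        report["mean_automated_total_cm3"] = float(tot.mean())
        report["sd_automated_total_cm3"] = float(tot.std(ddof=1)) if len(tot) > 1 else 0.0
    return report


def plot_agreement(pairs: PairedVolumes, quantity: str, file_path, loa_multiplier: float = 1.96) -> None:
    """Two-panel figure: scatter with regression line, and Bland–Altman plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pairs.subset(quantity)
    x = sub["reference_cm3"].to_numpy(float)
    y = sub["automated_cm3"].to_numpy(float)
    reg = fit_regression(pairs, quantity)
    ba = bland_altman(pairs, quantity, loa_multiplier)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.2))
    ax1.scatter(x, y, s=18, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 50)
    ax1.plot(xs, reg.slope * xs + reg.intercept, "r-",
             label=f"y = {reg.slope:.2f}x + {reg.intercept:.2f}, R² = {reg.r_squared:.2f}")
    ax1.set_xlabel("reference volume (cm³)")
    ax1.set_ylabel("automated volume (cm³)")
    ax1.set_title(f"{quantity} volume")
    ax1.legend(fontsize=8)

    mean_av = (x + y) / 2.0
    diff = y - x
    ax2.scatter(mean_av, diff, s=18, alpha=0.8)
    ax2.axhline(ba.bias, color="k", label=f"bias {ba.bias:.2f} cm³")
    for lim in (ba.loa_low, ba.loa_high):
        ax2.axhline(lim, color="k", linestyle="--")
    ax2.set_xlabel("mean of methods (cm³)")
    ax2.set_ylabel("automated − reference (cm³)")
    ax2.set_title("Bland–Altman")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(str(file_path), dpi=120)
    plt.close(fig)
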