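"""Cohort model and joint-line prediction.

The clinically useful output of the morphometry is a table of four
dimensionless ratios — each epicondyle-to-joint-line distance divided by
the femoral width ML — which are stable across patients.  Multiplying a
patient's (intra-operatively or software-) measured ML by a ratio predicts
where the lost articular surface used to be, e.g. for a 67 mm femur the
distal joint line lies ``67 x 0.33 = 22 mm`` distal to the medial
epicondyle and the posterior joint line ``67 x 0.39 = 26 mm`` posterior to
it.

:class:`JointLineModel` wraps a per-knee measurement table and its
:meth:`~JointLineModel.fit` returns a :class:`JointLineResults` carrying
summary statistics with confidence intervals, distance-vs-width Pearson
correlations, the fitted ratio table, reliability ICCs (when repeated
ratings are supplied) and the post hoc power of the correlation test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measure import (
    DISTANCE_NAMES,
    RATIO_NAMES,
    KneeMeasurement,
    measurements_to_dataframe,
)
from .stats import (
    CorrelationResult,
    ICCResult,
    InsufficientDataError,
    PowerSpec,
    SummaryStat,
    correlation_power,
    icc_absolute_agreement,
    pearson,
    summarize,
)

__all__ = [
    "RatioTable",
    "JLPrediction",
    "predict_offsets",
    "default_ratio_table",
    "cohort_ratio_table",
    "round_half_up",
    "JointLineModel",
    "JointLineResults",
]

#: study cohort ratio means (n = 127 CT knees): ME-FJ/ML, LE-FJ/ML, ME-EJ/ML, LE-EJ/ML
STUDY_RATIOS = (0.39, 0.28, 0.33, 0.28)

_OFFSET_LABELS = {
    "ratio_me_fj": "me_posterior",
    "ratio_le_fj": "le_posterior",
    "ratio_me_ej": "me_distal",
    "ratio_le_ej": "le_distal",
}


@dataclass(frozen=True)
class RatioTable:
    """Joint-line offset per unit femoral width."""

    ratio_me_fj: float
    ratio_le_fj: float
    ratio_me_ej: float
    ratio_le_ej: float
    source: str = "user"

    def __post_init__(self):
        for name in RATIO_NAMES:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}

    def to_json(self) -> str:
        return json.dumps({**self.as_dict(), "source": self.source}, indent=2)


def default_ratio_table() -> RatioTable:
    """The study cohort's mean ratios."""
    return RatioTable(*STUDY_RATIOS, source="study defaults")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from floor (22.5 -> 23)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class JLPrediction:
    """Predicted joint-line offsets (mm) for one femoral width."""

    ml: float
    offsets: dict
    offsets_rounded: dict
    ratios: RatioTable

    def describe(self) -> str:
        lines = [f"ML = {self.ml:.1f} mm (ratios: {self.ratios.source})"]
        for key, label in _OFFSET_LABELS.items():
            lines.append(
                f"  {label:13s} {self.offsets[label]:6.2f} mm "
                f"(~{self.offsets_rounded[label]} mm, ratio {getattr(self.ratios, key):.2f})"
            )
        return "\n".join(lines)


def predict_offsets(ml: float, ratios: RatioTable | None = None) -> JLPrediction:
    """Predict the four epicondyle-to-joint-line offsets from femoral width.

    Each offset is ``ml`` times the corresponding ratio; the rounded values
    (half-up to integer mm) are what a surgical plan would quote.
    """
    if ml <= 0:
        raise ValueError("femoral width ml must be positive")
    ratios = ratios or default_ratio_table()
    offsets = {
        label: ml * getattr(ratios, key) for key, label in _OFFSET_LABELS.items()
    }
    return JLPrediction(
        ml=float(ml),
        offsets=offsets,
        offsets_rounded={k: round_half_up(v) for k, v in offsets.items()},
        ratios=ratios,
    )


def cohort_ratio_table(measurements) -> RatioTable:
    """Mean per-knee ratios of a measured cohort."""
    measurements = list(measurements)
    if len(measurements) < 2:
        raise InsufficientDataError("cohort ratio table needs >= 2 knees")
    means = {
        name: float(np.mean([getattr(m, name) for m in measurements]))
        for name in RATIO_NAMES
    }
    return RatioTable(**means, source=f"cohort (n={len(measurements)})")


class JointLineModel:
    """Statistical model of a measured cohort of knees.

    Parameters
    ----------
    data
        Per-knee table with columns ``me_fj, le_fj, me_ej, le_ej, ml``
        (mm).  Ratio columns are computed if absent.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        missing = [c for c in DISTANCE_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"data lacks required columns: {missing}")
        if (df["ml"] <= 0).any():
            raise ValueError("ml must be positive for every knee")
        for dname, rname in zip(DISTANCE_NAMES[:4], RATIO_NAMES):
            df[rname] = df[dname] / df["ml"]
        self.data = df

    @classmethod
    def from_measurements(cls, measurements: list[KneeMeasurement]) -> "JointLineModel":
        return cls(measurements_to_dataframe(measurements))

    @classmethod
    def from_csv(cls, path) -> "JointLineModel":
        return cls(pd.read_csv(path))

    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(
        self,
        icc_ratings: dict[str, np.ndarray] | None = None,
        power_rho: float = 0.3,
        power_alpha: float = 0.05,
        power_method: str = "exact",
    ) -> "JointLineResults":
        """Compute summaries, correlations, ratio table, ICCs and power.

        ``power_rho`` is the smallest correlation the study is sized to
        detect; the default 0.3 corresponds to a conventional post hoc
        check of a weak-to-moderate effect.
        """
        df = self.data
        summaries = {c: summarize(df[c]) for c in DISTANCE_NAMES + RATIO_NAMES}
        correlations = {
            c: pearson(df["ml"], df[c]) for c in DISTANCE_NAMES[:4] + RATIO_NAMES
        }
        ratio_table = RatioTable(
            **{c: summaries[c].mean for c in RATIO_NAMES},
            source=f"cohort (n={self.nobs})",
        )
        power = correlation_power(
            PowerSpec(rho=power_rho, alpha=power_alpha, n=self.nobs, method=power_method)
        )
        iccs = (
            {k: icc_absolute_agreement(v) for k, v in icc_ratings.items()}
            if icc_ratings
            else {}
        )
        return JointLineResults(
            model=self,
            summaries=summaries,
            correlations=correlations,
            ratio_table=ratio_table,
            power=power,
            power_spec=PowerSpec(
                rho=power_rho, alpha=power_alpha, n=self.nobs, method=power_method
            ),
            iccs=iccs,
        )


@dataclass(frozen=True, eq=False)
class JointLineResults:
    """Fitted cohort statistics; produced by :meth:`JointLineModel.fit`."""

    model: JointLineModel
    summaries: dict[str, SummaryStat]
    correlations: dict[str, CorrelationResult]
    ratio_table: RatioTable
    power: float
    power_spec: PowerSpec
    iccs: dict[str, ICCResult]

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, ml: float) -> JLPrediction:
        """Joint-line offsets for a new femur of width ``ml`` using the fitted ratios."""
        return predict_offsets(ml, self.ratio_table)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in DISTANCE_NAMES + RATIO_NAMES:
            s = self.summaries[name]
            c = self.correlations.get(name)
            rows.append(
                {
                    "parameter": name,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                    "r_vs_ml": c.r if c else np.nan,
                    "p_vs_ml": c.p_two_sided if c else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report in the style of the cohort results table."""
        lines = [
            f"Joint-line morphometry cohort summary (n = {self.nobs} knees)",
            "",
            f"{'parameter':>12s}  {'mean ± SD (95% CI)':>34s}  {'r vs ML':>8s}  {'p':>8s}",
        ]
        for name in DISTANCE_NAMES:
            s = self.summaries[name]
            c = self.correlations.get(name)
            rs = f"{c.r:8.3f}" if c else "     n/a"
            ps = (
                "   <0.01" if c and c.p_two_sided < 0.01 else
                (f"{c.p_two_sided:8.3f}" if c else "     n/a")
            )
            lines.append(f"{name:>12s}  {s.display():>34s}  {rs}  {ps}")
        lines.append("")
        for name in RATIO_NAMES:
            s = self.summaries[name]
            lines.append(f"{name:>12s}  {s.display(decimals=2):>34s}")
        lines.append("")
        ps = self.power_spec
        lines.append(
            f"Post hoc power ({ps.method}, rho={ps.rho}, alpha={ps.alpha}, "
            f"two-tailed, n={ps.n}): {self.power * 100:.1f}%"
        )
        for key, icc in self.iccs.items():
            lines.append(f"ICC [{key}]: {icc.icc:.3f} ({icc.model})")
        return "\n".join(lines)

    def plot_correlation(self, parameter: str = "me_fj", ax=None):
        """Scatter of a distance against femoral width with the fitted trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.data["ml"]
        y = self.model.data[parameter]
        ax.scatter(x, y, s=12, alpha=0.7)
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        c = self.correlations[parameter]
        ax.plot(xs, a + b * xs, color="crimson",
                label=f"r = {c.r:.3f} (p = {c.p_two_sided:.2g})")
        ax.set_xlabel("ML, femoral width (mm)")
        ax.set_ylabel(f"{parameter} (mm)")
        ax.legend()
        return ax
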