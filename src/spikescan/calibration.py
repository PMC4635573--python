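"""Linear trait-to-SNPP calibration and its accuracy statistics.

Spikelet number per panicle (SNPP) is proportional to the branch-region
traits measured from the scan — both the total branch-region area and
TLPB2, the summed moment-ellipse major axes.  A variety-specific line

    SNPP = slope * trait + intercept

is therefore fitted either to 80% of the labeled samples (random split)
or, much faster in practice, to just five samples chosen uniformly
across the trait scale (the 5-point calibration), and used to predict
the remaining panicles.

Accuracy statistics:

* per-panicle estimation error  |SNPP_cal − SNPP_manual| / SNPP_manual × 100,
  summarized by the percentage of samples under 5% and under 10% error;
* SNPS deviation — the signed relative deviation of the mean estimated
  count from the mean manual count, (mean_cal − mean_true) / mean_true × 100.
  SNPS (spikelet number per square) is a mean over panicles, so the
  deviation compares means, never the mean of per-sample errors.

Samples used to fit a model are always excluded from its evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "ErrorReport",
    "select_calibration_points",
    "fit_line",
    "predict_snpp",
    "estimation_error",
    "error_range_table",
    "snps_deviation",
    "calibrate",
    "evaluate",
    "calibrate_and_evaluate",
]

TRAITS = ("area", "tlpb2")


@dataclass
class CalibrationModel:
    """A fitted trait→SNPP line."""

    trait: str                      # "area" or "tlpb2"
    slope: float                    # spikelets per trait unit
    intercept: float                # spikelets
    r_squared: float
    n_points: int
    trait_range: tuple[float, float]
    pixel_scale_dpi: float | None = None

    def to_json(self) -> str:
        d = {
            "trait": self.trait,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "trait_range": list(self.trait_range),
            "pixel_scale_dpi": self.pixel_scale_dpi,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            trait=d["trait"],
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            n_points=int(d["n_points"]),
            trait_range=(float(d["trait_range"][0]), float(d["trait_range"][1])),
            pixel_scale_dpi=d.get("pixel_scale_dpi"),
        )


def select_calibration_points(
    samples: Sequence[tuple[str, float]],
    k: int = 5,
    strategy: str = "value_uniform",
    seed: int | None = None,
) -> list[str]:
    """Choose ``k`` calibration samples spread over the trait scale.

    ``value_uniform`` (the default, and the intended reading of "chosen
    uniformly throughout the entire scale"): for each of the k targets
    min + j*(max-min)/(k-1) pick the unused sample whose trait value is
    nearest; ties go to the lower trait value.  The samples attaining the
    minimum and maximum are always among the selection.

    ``rank_uniform`` picks evenly spaced order statistics; ``random``
    picks k samples at random (requires ``seed`` for reproducibility).
    """
    ids = [s[0] for s in samples]
    values = np.asarray([s[1] for s in samples], dtype=float)
    if len(ids) < k:
        raise ValueError("insufficient calibration spread: fewer than k samples")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("insufficient calibration spread: zero trait range")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        return [ids[i] for i in sorted(rng.choice(len(ids), size=k, replace=False))]
    if strategy == "rank_uniform":
        order = np.argsort(values, kind="stable")
        picks = np.unique(np.round(np.linspace(0, len(ids) - 1, k)).astype(int))
        return [ids[order[i]] for i in picks]
    if strategy != "value_uniform":
        raise ValueError(f"unknown selection strategy {strategy!r}")

    targets = np.linspace(lo, hi, k)
    chosen: list[int] = []
    used = np.zeros(len(ids), dtype=bool)
    for t in targets:
        dist = np.abs(values - t)
        dist[used] = np.inf
        best = np.min(dist)
        # among nearest candidates take the lowest trait value (then first id)
        cand = np.flatnonzero(dist == best)
        pick = cand[np.argmin(values[cand])]
        chosen.append(int(pick))
        used[pick] = True
    return [ids[i] for i in chosen]


def fit_line(
    points: Sequence[tuple[float, float]],
    trait: str = "area",
    pixel_scale_dpi: float | None = None,
) -> CalibrationModel:
    """Ordinary least-squares fit of SNPP on a trait.

    ``points`` is a sequence of (trait value, snpp) pairs.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant trait values")
    res = stats.linregress(x, y)
    return CalibrationModel(
        trait=trait,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(x.size),
        trait_range=(float(x.min()), float(x.max())),
        pixel_scale_dpi=pixel_scale_dpi,
    )


def predict_snpp(model: CalibrationModel, trait_value: float) -> float:
    """Predict SNPP from a trait value, floored at zero.

    Warns (does not fail) when extrapolating outside the trait range the
    model was fitted on.
    """
    lo, hi = model.trait_range
    if not lo <= trait_value <= hi:
        warnings.warn(
            f"trait value {trait_value:g} outside calibration range [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    return max(model.slope * trait_value + model.intercept, 0.0)


def estimation_error(snpp_manual: float, snpp_cal: float) -> float:
    """Absolute per-panicle relative error, percent."""
    if snpp_manual <= 0:
        raise ValueError("estimation error undefined for non-positive manual count")
    return abs(snpp_cal - snpp_manual) / snpp_manual * 100.0


def error_range_table(
    errors: Iterable[float], thresholds: Sequence[float] = (5.0, 10.0)
) -> dict[float, float]:
    """Percentage of samples with error strictly below each threshold."""
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("no errors to summarize")
    return {float(t): float((e < t).mean() * 100.0) for t in thresholds}


def snps_deviation(true_mean: float, cal_mean: float) -> float:
    """Signed relative deviation of the estimated mean SNPP (the SNPS
    estimate) from the manual mean, percent."""
    if true_mean <= 0:
        raise ValueError("SNPS deviation undefined for non-positive true mean")
    return (cal_mean - true_mean) / true_mean * 100.0


@dataclass
class ErrorReport:
    """Held-out accuracy of one calibration model."""

    per_sample: list[tuple[str, float, float, float]]  # id, manual, cal, error %
    frac_within_5: float
    frac_within_10: float
    snps_true: float
    snps_cal: float
    deviation_pct: float
    train_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.per_sample)

    def summary(self) -> dict:
        return {
            "n": self.n,
            "frac_within_5": self.frac_within_5,
            "frac_within_10": self.frac_within_10,
            "snps_true": self.snps_true,
            "snps_cal": self.snps_cal,
            "deviation_pct": self.deviation_pct,
            "seed": self.seed,
        }


def _as_samples(samples) -> list[tuple[str, float, float]]:
    """Normalize input to a list of (id, trait value, snpp_manual)."""
    out = []
    for s in samples:
        sid, x, y = s
        out.append((str(sid), float(x), float(y)))
    return out


def calibrate(
    samples: Sequence[tuple[str, float, float]],
    *,
    trait: str = "area",
    mode: str = "five_point",
    k: int = 5,
    seed: int | None = None,
    strategy: str = "value_uniform",
    pixel_scale_dpi: float | None = None,
) -> tuple[CalibrationModel, list[str]]:
    """Fit a calibration model and return it with the training ids.

    ``samples`` is a sequence of (panicle_id, trait value, snpp_manual).
    ``mode`` is ``five_point`` (k samples uniform over the trait scale)
    or ``split_80_20`` (random 80% of samples; requires ``seed`` for a
    reproducible split).
    """
    rows = _as_samples(samples)
    if mode == "five_point":
        train_ids = select_calibration_points(
            [(sid, x) for sid, x, _ in rows], k=k, strategy=strategy, seed=seed
        )
    elif mode == "split_80_20":
        rng = np.random.default_rng(seed)
        n_train = max(int(round(0.8 * len(rows))), 2)
        idx = rng.permutation(len(rows))[:n_train]
        train_ids = [rows[i][0] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    train = {sid for sid in train_ids}
    pts = [(x, y) for sid, x, y in rows if sid in train]
    model = fit_line(pts, trait=trait, pixel_scale_dpi=pixel_scale_dpi)
    return model, train_ids


def evaluate(
    samples: Sequence[tuple[str, float, float]],
    model: CalibrationModel,
    train_ids: Iterable[str],
    *,
    round_predictions: bool = False,
    seed: int | None = None,
) -> ErrorReport:
    """Score a model on held-out samples.

    ``samples`` must be disjoint from ``train_ids``; an overlap raises,
    because samples used to establish a model must never be used to
    compute its estimation error.
    """
    rows = _as_samples(samples)
    train = set(str(t) for t in train_ids)
    overlap = train & {sid for sid, _, _ in rows}
    if overlap:
        raise ValueError(
            f"evaluation samples overlap the calibration set: {sorted(overlap)[:5]}"
        )
    if not rows:
        raise ValueError("no evaluation samples")
    per_sample = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warnings per-sample
        for sid, x, manual in rows:
            cal = predict_snpp(model, x)
            if round_predictions:
                cal = float(round(cal))
            per_sample.append((sid, manual, cal, estimation_error(manual, cal)))
    errors = [e for _, _, _, e in per_sample]
    within = error_range_table(errors)
    true_mean = float(np.mean([m for _, m, _, _ in per_sample]))
    cal_mean = float(np.mean([c for _, _, c, _ in per_sample]))
    return ErrorReport(
        per_sample=per_sample,
        frac_within_5=within[5.0],
        frac_within_10=within[10.0],
        snps_true=true_mean,
        snps_cal=cal_mean,
        deviation_pct=snps_deviation(true_mean, cal_mean),
        train_ids=sorted(train),
        seed=seed,
    )


def calibrate_and_evaluate(
    samples: Sequence[tuple[str, float, float]],
    *,
    trait: str = "area",
    mode: str = "five_point",
    k: int = 5,
    seed: int | None = None,
    strategy: str = "value_uniform",
    round_predictions: bool = False,
) -> tuple[CalibrationModel, ErrorReport]:
    """Fit on a calibration subset, evaluate on everything else."""
    rows = _as_samples(samples)
    model, train_ids = calibrate(
        rows, trait=trait, mode=mode, k=k, seed=seed, strategy=strategy
    )
    train = set(train_ids)
    holdout = [r for r in rows if r[0] not in train]
    report = evaluate(
        holdout, model, train_ids, round_predictions=round_predictions, seed=seed
    )
    return model, report
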