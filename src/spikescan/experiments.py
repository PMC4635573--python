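"""End-to-end simulation experiments: synthetic scans in, accuracy out.

These drive the whole chain — render synthetic varieties, segment each
scan, measure the branch traits, fit the 5-point (or 80/20) calibration
per variety, and score predictions on the held-out panicles — exactly
the protocol used to validate the method, but on images with known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibration import CalibrationModel, ErrorReport, calibrate_and_evaluate
from .segmentation import extract_branch_regions
from .synthetic import SyntheticGroundTruth, SyntheticPanicleSpec, generate_variety
from .traits import measure_panicle

__all__ = ["VarietyResult", "measure_variety", "run_snpp_trial", "DEFAULT_MEAN_SNPPS"]

# six varieties spanning small japonica-like to large indica-like panicles
DEFAULT_MEAN_SNPPS = (90.0, 110.0, 105.0, 90.0, 185.0, 200.0)


@dataclass
class VarietyResult:
    variety: str
    model: CalibrationModel
    report: ErrorReport
    traits: pd.DataFrame


def measure_variety(
    seed: int,
    n_panicles: int,
    mean_snpp: float,
    *,
    variety: str = "",
    dpi: float = 72.0,
    density_cv: float = 0.07,
    snpp_spread: float = 0.2,
) -> pd.DataFrame:
    """Render one synthetic variety and push every scan through the
    segmentation + trait pipeline.

    Returns one row per panicle: measured traits plus the true SNPP as
    the manual-count stand-in (the generator plays the human counter).
    """
    spec = SyntheticPanicleSpec(seed=seed, dpi=dpi, density_cv=density_cv)
    rows = []
    for i, (img, truth) in enumerate(
        generate_variety(spec, n_panicles, mean_snpp, snpp_spread=snpp_spread)
    ):
        seg = extract_branch_regions(img)
        m = measure_panicle(
            seg.labels,
            seg.n_regions,
            dpi=dpi,
            panicle_id=f"{variety}{i:03d}",
            variety=variety,
            snpp_manual=truth.snpp,
        )
        rows.append(
            {
                "panicle_id": m.panicle_id,
                "variety": variety,
                "n_regions": m.n_regions,
                "total_area_px": m.total_area_px,
                "tlpb2_px": m.tlpb2_px,
                "snpp_manual": truth.snpp,
                "true_total_length_px": truth.total_length_px,
                "true_n_branches": len(truth.branches),
            }
        )
    return pd.DataFrame(rows)


def run_snpp_trial(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    n_panicles: int = 100,
    mean_snpps: tuple[float, ...] = DEFAULT_MEAN_SNPPS,
    *,
    trait: str = "area",
    mode: str = "five_point",
    k: int = 5,
    density_cv: float = 0.07,
) -> list[VarietyResult]:
    """Full accuracy trial: one 5-point calibration per synthetic variety,
    evaluated on the panicles not used for calibration."""
    if len(seeds) != len(mean_snpps):
        raise ValueError("need one seed per variety")
    trait_col = {"area": "total_area_px", "tlpb2": "tlpb2_px"}[trait]
    results = []
    for v, (seed, mean_snpp) in enumerate(zip(seeds, mean_snpps)):
        name = chr(ord("A") + v)
        df = measure_variety(
            seed, n_panicles, mean_snpp, variety=name, density_cv=density_cv
        )
        samples = list(
            zip(df["panicle_id"], df[trait_col].astype(float), df["snpp_manual"])
        )
        model, report = calibrate_and_evaluate(
            samples, trait=trait, mode=mode, k=k, seed=seed
        )
        results.append(VarietyResult(variety=name, model=model, report=report, traits=df))
    return results
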