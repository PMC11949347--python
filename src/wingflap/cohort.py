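"""Synthetic hen cohorts: correlated morphometrics plus one flap
configuration per hen.

The four body measures (weight and three wing lengths) are drawn from a
Gaussian copula with Gaussian marginals, so any pairwise correlation
structure can be planted (including none, matching the null-looking table
the measurement this emulates reported).  The flap kinematics of each hen
are tied loosely to her anatomy — the wing panel length is the skeletal
extended-wing measure — while shoulder height and the peak elevation angle
vary independently between hens, which keeps the measured flap height only
weakly coupled to any single body measure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .io import HenMorphometrics, write_morphometrics, write_sequence
from .rig import CameraRig, FlapConfig
from .synthetic import generate_sequence

#: marginal (mean, SD) of each measure; plausible values for a mature
#: white egg-laying strain, not published measurements
DEFAULT_MARGINALS = {
    "weight_kg": (1.56, 0.10),
    "folded_wing_cm": (19.0, 1.2),
    "extended_primary_cm": (29.0, 1.8),
    "extended_phalange_cm": (21.0, 1.4),
}
MEASURE_ORDER = list(DEFAULT_MARGINALS)


@dataclass
class CohortMember:
    record: HenMorphometrics          # max_height_cm left unset
    flap: FlapConfig
    true_peak_height: float           # analytic bout maximum, cm


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
        raise ValueError("corr must be a symmetric 4x4 matrix over "
                         f"{MEASURE_ORDER}")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("corr must have unit diagonal")
    try:
        np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    except np.linalg.LinAlgError:
        raise ValueError("corr is not positive semi-definite")
    return corr


def planted_correlation(pairs: dict) -> np.ndarray:
    """Identity correlation with specific pairs planted, e.g.
    ``{("weight_kg", "extended_phalange_cm"): 0.9}``."""
    corr = np.eye(4)
    idx = {v: i for i, v in enumerate(MEASURE_ORDER)}
    for (a, b), rho in pairs.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return _check_correlation(corr)


def make_fixture_cohort(
    n_hens: int,
    seed: int,
    corr: Optional[np.ndarray] = None,
    duration: float = 2.0,
    noise_sigma: float = 0.3,
    dropout_rate: float = 0.02,
    flap_frequency: float = 4.0,
) -> List[CohortMember]:
    """Draw ``n_hens`` correlated morphometric records and flap configs.

    Per-hen kinematics: wing panel length equals the skeletal
    extended-wing measure; shoulder height ~ N(30, 3) cm and peak wing
    elevation ~ N(72, 8) degrees vary independently between hens.
    Deterministic for a given seed.
    """
    if n_hens < 1:
        raise ValueError("n_hens must be >= 1")
    corr = _check_correlation(np.eye(4) if corr is None else corr)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    z = rng.standard_normal((n_hens, 4)) @ L.T

    members = []
    for i in range(n_hens):
        vals = {}
        for j, name in enumerate(MEASURE_ORDER):
            mu, sd = DEFAULT_MARGINALS[name]
            vals[name] = mu + sd * z[i, j]
        vals["weight_kg"] = max(vals["weight_kg"], 0.8)
        vals["folded_wing_cm"] = max(vals["folded_wing_cm"], 10.0)
        vals["extended_phalange_cm"] = float(np.clip(vals["extended_phalange_cm"], 14.0, 28.0))
        # feathers extend past bone: keep records physically consistent
        vals["extended_primary_cm"] = max(vals["extended_primary_cm"],
                                          vals["extended_phalange_cm"] + 0.3)

        shoulder = float(np.clip(rng.normal(30.0, 3.0), 22.0, 38.0))
        peak = float(np.clip(rng.normal(72.0, 8.0), 40.0, 89.0))
        flap = FlapConfig(
            shoulder_height=shoulder,
            standing_height=shoulder + 4.0,
            wing_length=vals["extended_phalange_cm"],
            rest_angle=10.0,
            peak_angle=peak,
            flap_frequency=flap_frequency,
            duration=duration,
            noise_sigma=noise_sigma,
            dropout_rate=dropout_rate,
            seed=int(rng.integers(2 ** 31)),
        )
        rec = HenMorphometrics(hen_id=f"hen_{i + 1:02d}", **vals).validate()
        members.append(CohortMember(rec, flap, flap.peak_tip_height))
    return members


def analytic_height_records(
    cohort: Sequence[CohortMember],
    measurement_sigma: float = 0.4,
    seed: int = 0,
) -> List[HenMorphometrics]:
    """Records with ``max_height_cm`` filled from the analytic bout peak
    plus Gaussian measurement error — a fast stand-in for running the full
    render-and-extract chain when only the statistics stage is exercised."""
    rng = np.random.default_rng(seed)
    out = []
    for m in cohort:
        r = HenMorphometrics(
            hen_id=m.record.hen_id,
            weight_kg=m.record.weight_kg,
            folded_wing_cm=m.record.folded_wing_cm,
            extended_primary_cm=m.record.extended_primary_cm,
            extended_phalange_cm=m.record.extended_phalange_cm,
            max_height_cm=m.true_peak_height + rng.normal(0.0, measurement_sigma),
        ).validate()
        out.append(r)
    return out


def write_cohort(
    cohort: Sequence[CohortMember],
    out_dir: Union[str, Path],
    rig: Optional[CameraRig] = None,
) -> Path:
    """Materialise a cohort on disk: morphometrics CSV plus one sequence
    directory per hen."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rig = rig or CameraRig()
    for m in cohort:
        bundle = generate_sequence(m.flap, rig, hen_id=m.record.hen_id)
        write_sequence(bundle, out_dir / m.record.hen_id)
    return write_morphometrics([m.record for m in cohort], out_dir / "morphometrics.csv")
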