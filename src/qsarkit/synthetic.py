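"""Seeded generators producing inputs with the statistical structure every
downstream stage assumes, so the whole pipeline is testable offline.

All generators are pure functions of their arguments: the same seed yields
byte-identical output.  Ground truth is always returned separately from the
observations so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qsarkit.core_data import Compound, QSARDataset, split_dataset
from qsarkit.mmgbsa import EnergyComponents
from qsarkit.screening import RankedScreen
from qsarkit.traj import Trajectory

__all__ = [
    "SimConfig",
    "default_correlation",
    "gen_qsar_dataset",
    "gen_ranked_screen",
    "gen_trajectory",
    "gen_mmgbsa_frames",
]

# defaults sized like the study's design: 28 compounds, 4 descriptors,
# 23/5 split, residual scale ~0.15
DEFAULT_COEFS = (-0.002, 52.0, 0.43, 0.28)
DEFAULT_INTERCEPT = 6.2


@dataclass
class SimConfig:
    seed: int = 0
    n_compounds: int = 28
    n_descriptors: int = 4
    true_intercept: float = DEFAULT_INTERCEPT
    true_coefs: tuple[float, ...] = DEFAULT_COEFS
    noise_sd: float = 0.15
    descriptor_correlation: np.ndarray | None = None
    n_test: int = 5

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_descriptors < 1:
            raise ValueError("sizes must be positive")
        if len(self.true_coefs) != self.n_descriptors:
            raise ValueError("true_coefs length must equal n_descriptors")


def default_correlation(p: int, max_r: float = 0.58) -> np.ndarray:
    """Mildly collinear target correlation: one strong pair, weak background."""
    corr = np.full((p, p), 0.2)
    np.fill_diagonal(corr, 1.0)
    if p >= 2:
        corr[0, 1] = corr[1, 0] = max_r
    return corr


def gen_qsar_dataset(config: SimConfig | None = None, **kwargs):
    """Linear-signal QSAR dataset with Gaussian noise.

    Returns ``(dataset with 23/5-style partition, ground_truth dict)`` where
    ground truth holds the intercept, coefficients, noise draws, and the clean
    activities.
    """
    if config is None:
        config = SimConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    p = config.n_descriptors
    corr = (
        np.asarray(config.descriptor_correlation, dtype=float)
        if config.descriptor_correlation is not None
        else default_correlation(p)
    )
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("descriptor correlation matrix is not positive-definite") from exc
    Z = rng.standard_normal((config.n_compounds, p))
    X = Z @ chol.T
    coefs = np.asarray(config.true_coefs, dtype=float)
    clean = config.true_intercept + X @ coefs
    noise = rng.normal(0.0, config.noise_sd, size=config.n_compounds)
    y = clean + noise
    names = [f"d{j + 1}" for j in range(p)]
    compounds = [
        Compound(
            id=f"cpd_{i + 1:03d}",
            descriptors={names[j]: float(X[i, j]) for j in range(p)},
            pic50=float(y[i]),
        )
        for i in range(config.n_compounds)
    ]
    dataset = QSARDataset(compounds, names)
    if 0 < config.n_test < config.n_compounds:
        dataset = split_dataset(dataset, n_test=config.n_test, seed=config.seed)
    ground_truth = {
        "intercept": config.true_intercept,
        "coefficients": dict(zip(names, coefs)),
        "noise_sd": config.noise_sd,
        "noise": noise,
        "clean_y": clean,
    }
    return dataset, ground_truth


def gen_ranked_screen(
    n_actives: int, n_decoys: int, separation: float, seed: int | None = 0
) -> RankedScreen:
    """Two-Gaussian screen: actives ~ N(separation, 1), decoys ~ N(0, 1)."""
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    entries = [
        (f"act_{i + 1:03d}", float(rng.normal(separation, 1.0)), True)
        for i in range(n_actives)
    ] + [
        (f"dec_{i + 1:03d}", float(rng.normal(0.0, 1.0)), False)
        for i in range(n_decoys)
    ]
    return RankedScreen.from_unsorted(entries)


def gen_trajectory(
    n_frames: int,
    n_atoms: int,
    jitter_sd: float,
    basins: int = 1,
    seed: int | None = 0,
    basin_offset: float = 4.0,
):
    """Reference geometry + optional basin-switching offset + Gaussian jitter.

    Returns ``(trajectory, reference coords, basin labels per frame)``.
    """
    if n_frames < 1 or n_atoms < 1:
        raise ValueError("sizes must be positive")
    if basins < 1:
        raise ValueError("basins must be >= 1")
    rng = np.random.default_rng(seed)
    reference = rng.uniform(-5.0, 5.0, size=(n_atoms, 3))
    labels = rng.integers(0, basins, size=n_frames) if basins > 1 else np.zeros(n_frames, dtype=int)
    offsets = np.zeros((basins, 3))
    for b in range(1, basins):
        offsets[b] = [b * basin_offset, 0.0, 0.0]
    coords = (
        reference[None, :, :]
        + offsets[labels][:, None, :]
        + rng.normal(0.0, jitter_sd, size=(n_frames, n_atoms, 3))
    )
    traj = Trajectory(coords=coords, masses=np.ones(n_atoms))
    return traj, reference, labels


def gen_mmgbsa_frames(
    means: dict[str, float],
    sds: dict[str, float],
    n_frames: int,
    seed: int | None = 0,
) -> list[EnergyComponents]:
    """I.i.d. normal per-component frames around the requested means."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    keys = ("vdwaals", "eel", "egb", "esurf")
    for k in keys:
        if k not in means or k not in sds:
            raise ValueError(f"means and sds must both define {k!r}")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        frames.append(
            EnergyComponents(
                vdwaals=float(rng.normal(means["vdwaals"], sds["vdwaals"])),
                eel=float(rng.normal(means["eel"], sds["eel"])),
                egb=float(rng.normal(means["egb"], sds["egb"])),
                esurf=float(rng.normal(means["esurf"], sds["esurf"])),
                frame=f,
            )
        )
    return frames
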