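"""Early-recognition metrics for ranked virtual screens.

A :class:`RankedScreen` is an ordered best-first list of (id, score, active)
entries.  Sorting is a stable descending sort on score, so input order is the
documented tie-break.  ROC AUC gives score ties 0.5 credit (Mann-Whitney
convention).  RIE/BEDROC follow Truchon & Bayly (2007).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RankedScreen",
    "EnrichmentReport",
    "label_actives",
    "roc_auc",
    "bedroc_rie",
    "enrichment_factor",
    "accumulation_curve",
    "actives_at_decoy_fraction",
    "enrichment_report",
    "read_screen_csv",
    "write_screen_csv",
]


@dataclass
class RankedScreen:
    """Ordered screen: ``entries[k] = (ligand_id, score, active)``, best first."""

    entries: list[tuple[str, float, bool]]

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("entries must be sorted best-first (descending score)")

    @classmethod
    def from_unsorted(cls, entries) -> "RankedScreen":
        """Stable descending sort on score; input order breaks ties."""
        ordered = sorted(entries, key=lambda e: -float(e[1]))
        return cls([(str(i), float(s), bool(a)) for i, s, a in ordered])

    @property
    def n_total(self) -> int:
        return len(self.entries)

    @property
    def n_actives(self) -> int:
        return sum(1 for _, _, a in self.entries if a)

    @property
    def n_decoys(self) -> int:
        return self.n_total - self.n_actives

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based ranks of the active entries."""
        return np.array([i + 1 for i, (_, _, a) in enumerate(self.entries) if a])

    def _require_both_classes(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ValueError("screen must contain at least one active and one decoy")


def label_actives(pic50_values, threshold: float = 6.5) -> list[bool]:
    """Active iff pIC50 strictly exceeds the threshold."""
    values = np.asarray(pic50_values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("pIC50 values must be finite")
    return [bool(v > threshold) for v in values]


def roc_auc(screen: RankedScreen) -> float:
    """Probability a random active outranks a random decoy (ties get 0.5)."""
    screen._require_both_classes()
    scores = np.array([s for _, s, _ in screen.entries])
    active = np.array([a for _, _, a in screen.entries])
    ranks = scipy.stats.rankdata(scores)  # average ranks handle ties
    n_a, n_d = screen.n_actives, screen.n_decoys
    u = ranks[active].sum() - n_a * (n_a + 1) / 2.0
    return float(u / (n_a * n_d))


def bedroc_rie(screen: RankedScreen, alpha: float = 160.9) -> tuple[float, float]:
    """(BEDROC, RIE) per Truchon & Bayly; BEDROC is bounded in [0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    screen._require_both_classes()
    N = screen.n_total
    n = screen.n_actives
    ranks = screen.active_ranks
    ra = n / N
    # RIE: observed sum of exponential weights over the uniform expectation
    observed = float(np.sum(np.exp(-alpha * ranks / N)))
    expected = (n / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    rie = observed / expected
    # min-max normalization to BEDROC
    bedroc = rie * ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    ) + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return float(bedroc), float(rie)


def enrichment_factor(screen: RankedScreen, top_fraction: float) -> float:
    """EF(f) = (actives in top ceil(f*N) / n_actives) / f."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    screen._require_both_classes()
    n_top = math.ceil(top_fraction * screen.n_total)
    if n_top == 0:
        raise ValueError("top slice is empty")
    hits = sum(1 for _, _, a in screen.entries[:n_top] if a)
    return (hits / screen.n_actives) / top_fraction


def accumulation_curve(screen: RankedScreen) -> tuple[np.ndarray, np.ndarray, float]:
    """(fraction screened, fraction of actives found, trapezoid AUAC)."""
    screen._require_both_classes()
    active = np.array([a for _, _, a in screen.entries], dtype=float)
    x = np.arange(0, screen.n_total + 1) / screen.n_total
    yvals = np.concatenate([[0.0], np.cumsum(active) / screen.n_actives])
    auac = float(np.trapezoid(yvals, x))
    return x, yvals, auac


def actives_at_decoy_fraction(screen: RankedScreen, decoy_fraction: float = 0.2) -> float:
    """Percent of actives seen before the rank at which ``ceil(f * n_decoys)``
    decoys have been retrieved."""
    if not 0 < decoy_fraction <= 1:
        raise ValueError("decoy_fraction must be in (0, 1]")
    if screen.n_decoys == 0:
        raise ValueError("screen contains no decoys")
    needed = math.ceil(decoy_fraction * screen.n_decoys)
    decoys_seen = 0
    actives_seen = 0
    for _, _, active in screen.entries:
        if active:
            actives_seen += 1
        else:
            decoys_seen += 1
            if decoys_seen == needed:
                break
    if screen.n_actives == 0:
        raise ValueError("screen contains no actives")
    return 100.0 * actives_seen / screen.n_actives


@dataclass
class EnrichmentReport:
    roc_auc: float
    bedroc: float
    rie: float
    alpha: float
    ef: dict[float, float]
    auac: float
    actives_at_decoy_fraction: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "bedroc": self.bedroc,
            "rie": self.rie,
            "alpha": self.alpha,
            "ef": {str(f): v for f, v in self.ef.items()},
            "auac": self.auac,
            "actives_at_decoy_fraction": {
                str(f): v for f, v in self.actives_at_decoy_fraction.items()
            },
        }


def enrichment_report(
    screen: RankedScreen,
    alpha: float = 160.9,
    ef_fractions: tuple[float, ...] = (0.01, 0.05, 0.2),
    decoy_fractions: tuple[float, ...] = (0.2,),
) -> EnrichmentReport:
    """All early-recognition metrics in one report."""
    bedroc, rie = bedroc_rie(screen, alpha=alpha)
    _, _, auac = accumulation_curve(screen)
    return EnrichmentReport(
        roc_auc=roc_auc(screen),
        bedroc=bedroc,
        rie=rie,
        alpha=alpha,
        ef={f: enrichment_factor(screen, f) for f in ef_fractions},
        auac=auac,
        actives_at_decoy_fraction={
            f: actives_at_decoy_fraction(screen, f) for f in decoy_fractions
        },
    )


def read_screen_csv(path) -> RankedScreen:
    """Read ``id,score,active`` (active as 0/1) and rank best-first."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "score", "active"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df[["score", "active"]].isna().any().any():
        raise ValueError("missing values in score/active columns")
    return RankedScreen.from_unsorted(
        [(r["id"], float(r["score"]), bool(int(r["active"]))) for _, r in df.iterrows()]
    )


def write_screen_csv(screen: RankedScreen, path) -> None:
    pd.DataFrame(
        [
            {"id": i, "score": repr(s), "active": int(a)}
            for i, s, a in screen.entries
        ]
    ).to_csv(path, index=False)
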