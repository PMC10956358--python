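"""MM/GBSA component bookkeeping (kcal/mol, AMBER sign conventions).

Identities enforced and reported::

    g_gas  = vdwaals + eel
    g_solv = egb + esurf
    total  = g_gas + g_solv

Frame tables are CSVs with columns ``frame,VDWAALS,EEL,EGB,ESURF``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
import numpy as np

__all__ = [
    "EnergyComponents",
    "BindingEnergyReport",
    "binding_totals",
    "aggregate_frames",
    "read_component_table",
    "write_component_table",
]

_COLUMNS = ["VDWAALS", "EEL", "EGB", "ESURF"]


@dataclass
class EnergyComponents:
    vdwaals: float
    eel: float
    egb: float
    esurf: float
    frame: int | None = None

    def __post_init__(self) -> None:
        for name in ("vdwaals", "eel", "egb", "esurf"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"missing energy component {name!r}")
            if not math.isfinite(value):
                raise ValueError(f"energy component {name!r} is not finite: {value!r}")


@dataclass
class BindingEnergyReport:
    components: EnergyComponents
    g_gas: float
    g_solv: float
    total: float
    component_sds: EnergyComponents | None = None
    n_frames: int = 1

    def to_dict(self) -> dict:
        out = {
            "VDWAALS": self.components.vdwaals,
            "EEL": self.components.eel,
            "EGB": self.components.egb,
            "ESURF": self.components.esurf,
            "G_GAS": self.g_gas,
            "G_SOLV": self.g_solv,
            "TOTAL": self.total,
            "n_frames": self.n_frames,
        }
        if self.component_sds is not None:
            out["sd"] = {
                "VDWAALS": self.component_sds.vdwaals,
                "EEL": self.component_sds.eel,
                "EGB": self.component_sds.egb,
                "ESURF": self.component_sds.esurf,
            }
        return out


def binding_totals(components: EnergyComponents) -> BindingEnergyReport:
    """Total the four components into gas-phase, solvation, and overall terms."""
    g_gas = components.vdwaals + components.eel
    g_solv = components.egb + components.esurf
    return BindingEnergyReport(
        components=components,
        g_gas=g_gas,
        g_solv=g_solv,
        total=g_gas + g_solv,
    )


def aggregate_frames(frames: list[EnergyComponents]) -> BindingEnergyReport:
    """Component-wise mean +- sample sd over frames; totals taken on the means."""
    if not frames:
        raise ValueError("no frames to aggregate")
    arr = np.array([[f.vdwaals, f.eel, f.egb, f.esurf] for f in frames], dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros(4)
    sds[np.ptp(arr, axis=0) == 0] = 0.0  # identical frames: exactly zero spread
    report = binding_totals(EnergyComponents(*means))
    report.component_sds = EnergyComponents(*sds)
    report.n_frames = len(frames)
    return report


def read_component_table(path) -> list[EnergyComponents]:
    """Read per-frame components from ``frame,VDWAALS,EEL,EGB,ESURF``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ["frame"] + _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in _COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = df.index[
                df[col].isna() | ~df[col].apply(lambda v: isinstance(v, (int, float)))
            ].tolist()
            raise ValueError(f"non-numeric or missing value in column {col!r} at rows {bad}")
    return [
        EnergyComponents(
            vdwaals=float(r["VDWAALS"]),
            eel=float(r["EEL"]),
            egb=float(r["EGB"]),
            esurf=float(r["ESURF"]),
            frame=int(r["frame"]),
        )
        for _, r in df.iterrows()
    ]


def write_component_table(frames: list[EnergyComponents], path) -> None:
    pd.DataFrame(
        [
            {
                "frame": f.frame if f.frame is not None else i,
                "VDWAALS": repr(f.vdwaals),
                "EEL": repr(f.eel),
                "EGB": repr(f.egb),
                "ESURF": repr(f.esurf),
            }
            for i, f in enumerate(frames)
        ]
    ).to_csv(path, index=False)
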