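"""Rule-based drug-likeness filters over precomputed physicochemical tables.

Implemented rules (boundary comparisons inclusive):

* Lipinski: MW <= 500, logP <= 5, HBD <= 5, HBA <= 10; accepted with at most
  ``lipinski_max_violations`` violations (default 1, the rule-of-five
  convention; set 0 for a strict reading).
* Ghose: 160 <= MW <= 480, -0.4 <= logP <= 5.6, 40 <= MR <= 130,
  20 <= heavy atoms <= 70.
* Veber: rotatable bonds <= 10, TPSA <= 140.
* Egan: logP <= 5.88, TPSA <= 131.6.
* Muegge: 200 <= MW <= 600, -2 <= logP <= 5, TPSA <= 150, rings <= 7,
  rotatable bonds <= 15, HBA <= 10, HBD <= 5.

Properties are consumed, never computed; no structure perception happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PhyschemProfile", "RuleVerdict", "evaluate_rules", "evaluate_table"]

ALL_RULES = ("lipinski", "ghose", "veber", "egan", "muegge")


@dataclass
class PhyschemProfile:
    id: str
    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rot_bonds: int
    molar_refractivity: float | None = None
    heavy_atoms: int | None = None
    rings: int | None = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.id!r}: molecular weight must be positive")
        for name in ("hbd", "hba", "rot_bonds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.id!r}: {name} must be non-negative")


@dataclass
class RuleVerdict:
    rule: str
    accepted: bool
    violations: list[str]


def _require(profile: PhyschemProfile, rule: str, fields: list[str]) -> None:
    for f in fields:
        if getattr(profile, f) is None:
            raise ValueError(f"rule {rule!r} requires field {f!r} for {profile.id!r}")


def evaluate_rules(
    profile: PhyschemProfile,
    rules: tuple[str, ...] = ALL_RULES,
    lipinski_max_violations: int = 1,
) -> dict[str, RuleVerdict]:
    """Evaluate the requested rules; each verdict lists every violated sub-rule."""
    verdicts: dict[str, RuleVerdict] = {}
    for rule in rules:
        if rule == "lipinski":
            checks = [
                ("MW>500", profile.mw > 500),
                ("logP>5", profile.logp > 5),
                ("HBD>5", profile.hbd > 5),
                ("HBA>10", profile.hba > 10),
            ]
            violations = [name for name, bad in checks if bad]
            verdicts[rule] = RuleVerdict(
                rule, len(violations) <= lipinski_max_violations, violations
            )
        elif rule == "ghose":
            _require(profile, rule, ["molar_refractivity", "heavy_atoms"])
            checks = [
                ("MW<160", profile.mw < 160),
                ("MW>480", profile.mw > 480),
                ("logP<-0.4", profile.logp < -0.4),
                ("logP>5.6", profile.logp > 5.6),
                ("MR<40", profile.molar_refractivity < 40),
                ("MR>130", profile.molar_refractivity > 130),
                ("atoms<20", profile.heavy_atoms < 20),
                ("atoms>70", profile.heavy_atoms > 70),
            ]
            violations = [name for name, bad in checks if bad]
            verdicts[rule] = RuleVerdict(rule, not violations, violations)
        elif rule == "veber":
            checks = [
                ("RotB>10", profile.rot_bonds > 10),
                ("TPSA>140", profile.tpsa > 140),
            ]
            violations = [name for name, bad in checks if bad]
            verdicts[rule] = RuleVerdict(rule, not violations, violations)
        elif rule == "egan":
            checks = [
                ("logP>5.88", profile.logp > 5.88),
                ("TPSA>131.6", profile.tpsa > 131.6),
            ]
            violations = [name for name, bad in checks if bad]
            verdicts[rule] = RuleVerdict(rule, not violations, violations)
        elif rule == "muegge":
            _require(profile, rule, ["rings"])
            checks = [
                ("MW<200", profile.mw < 200),
                ("MW>600", profile.mw > 600),
                ("logP<-2", profile.logp < -2),
                ("logP>5", profile.logp > 5),
                ("TPSA>150", profile.tpsa > 150),
                ("rings>7", profile.rings > 7),
                ("RotB>15", profile.rot_bonds > 15),
                ("HBA>10", profile.hba > 10),
                ("HBD>5", profile.hbd > 5),
            ]
            violations = [name for name, bad in checks if bad]
            verdicts[rule] = RuleVerdict(rule, not violations, violations)
        else:
            raise ValueError(f"unknown rule {rule!r}; known: {ALL_RULES}")
    return verdicts


def evaluate_table(
    df: pd.DataFrame,
    rules: tuple[str, ...] = ("lipinski", "veber", "egan"),
    lipinski_max_violations: int = 1,
) -> pd.DataFrame:
    """Rule verdicts for every row of a property table (see CSV conventions)."""
    required = {"id", "mw", "logp", "hbd", "hba", "tpsa", "rot_bonds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"property table missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        profile = PhyschemProfile(
            id=str(r["id"]),
            mw=float(r["mw"]),
            logp=float(r["logp"]),
            hbd=int(r["hbd"]),
            hba=int(r["hba"]),
            tpsa=float(r["tpsa"]),
            rot_bonds=int(r["rot_bonds"]),
            molar_refractivity=float(r["molar_refractivity"])
            if "molar_refractivity" in df.columns
            else None,
            heavy_atoms=int(r["heavy_atoms"]) if "heavy_atoms" in df.columns else None,
            rings=int(r["rings"]) if "rings" in df.columns else None,
        )
        verdicts = evaluate_rules(profile, rules, lipinski_max_violations)
        row: dict[str, object] = {"id": profile.id}
        for rule, v in verdicts.items():
            row[rule] = "accept" if v.accepted else ";".join(v.violations)
        rows.append(row)
    return pd.DataFrame(rows)
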