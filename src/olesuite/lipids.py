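"""GC/MS peak tables -> internal-standard-quantified, OD-normalized profiles.

Olefins are quantified against a known amount of triacontane added to
the extraction solvent, FAMEs against eicosanoic acid; response factors
default to 1 (areas compared directly). Amounts are reported as
µg per mL culture per OD600 unit. Olefin branch state is one of
iso / anteiso / straight per chain end, giving six unordered end-pair
isomer classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BRANCH_TYPES = ("iso", "anteiso", "straight")
#: the six unordered end-pair classes, in conventional display order
ISOMER_CLASSES = ("isoiso", "isoai", "aiai", "isosc", "aisc", "scsc")

_END_CODE = {"iso": "iso", "anteiso": "ai", "straight": "sc"}
_CLASS_OF = {
    frozenset(["iso"]): "isoiso",
    frozenset(["iso", "anteiso"]): "isoai",
    frozenset(["anteiso"]): "aiai",
    frozenset(["iso", "straight"]): "isosc",
    frozenset(["anteiso", "straight"]): "aisc",
    frozenset(["straight"]): "scsc",
}

PEAK_COLUMNS = ("analyte_class", "chain_length", "branch1", "branch2", "area")


@dataclass(frozen=True)
class InternalStandardSpec:
    compound: str  # "triacontane" (olefins) or "eicosanoic_acid" (FAMEs)
    amount_ug: float

    def __post_init__(self):
        if self.compound not in ("triacontane", "eicosanoic_acid"):
            raise ValueError(f"unknown internal standard {self.compound!r}")
        if self.amount_ug <= 0:
            raise ValueError("internal standard amount must be positive")


# Extraction defaults: 4 mL hexane at 10 µg/mL triacontane for olefins;
# 0.5 mL of 100 µg/mL eicosanoic acid for FAMEs.
OLEFIN_IS_DEFAULT = InternalStandardSpec("triacontane", 4.0 * 10.0)
FAME_IS_DEFAULT = InternalStandardSpec("eicosanoic_acid", 0.5 * 100.0)


@dataclass(frozen=True)
class CultureContext:
    culture_volume_mL: float  # olefin workflow samples 10 mL, FAME 2.5 mL
    od600: float

    def __post_init__(self):
        if self.culture_volume_mL <= 0 or self.od600 <= 0:
            raise ValueError("culture volume and OD600 must be positive")


def classify_isomer(end1: str, end2: str) -> str:
    """Map the two chain-end branch states to one of the six isomer classes."""
    for end in (end1, end2):
        if end not in BRANCH_TYPES:
            raise ValueError(f"unknown branch type {end!r}")
    return _CLASS_OF[frozenset((end1, end2))]


@dataclass
class LipidProfile:
    """Amounts (µg · mL⁻¹ culture · OD⁻¹) indexed by (chain_length, isomer_class)."""

    amounts: pd.Series  # MultiIndex (chain_length, isomer_class)

    def __post_init__(self):
        if (self.amounts < 0).any():
            raise ValueError("amounts must be non-negative")
        self.amounts = self.amounts.groupby(level=[0, 1]).sum().sort_index()

    @property
    def total(self) -> float:
        return float(self.amounts.sum())

    def joint_distribution(self) -> pd.Series:
        if self.total <= 0:
            raise ValueError("profile has zero total amount")
        return self.amounts / self.total


def quantify(
    peaks: pd.DataFrame,
    is_spec: InternalStandardSpec,
    ctx: CultureContext,
    response_factors: dict[tuple[int, str], float] | None = None,
    analyte_class: str = "olefin",
) -> LipidProfile:
    """Internal-standard quantification with OD normalization.

    amount_i = (area_i / area_IS) * amount_IS / (response_i) / volume / OD.
    Exactly one internal_standard row with positive area is required;
    negative areas are an error.
    """
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    if (peaks["area"] < 0).any():
        raise ValueError("negative peak area")
    is_rows = peaks[peaks["analyte_class"] == "internal_standard"]
    if len(is_rows) != 1:
        raise ValueError(f"need exactly one internal_standard row, got {len(is_rows)}")
    area_is = float(is_rows["area"].iloc[0])
    if area_is <= 0:
        raise ValueError("internal standard area must be positive")
    response_factors = response_factors or {}
    rows = peaks[peaks["analyte_class"] == analyte_class]
    index = []
    values = []
    for _, row in rows.iterrows():
        chain = int(row["chain_length"])
        cls = classify_isomer(str(row["branch1"]), str(row["branch2"]))
        rf = response_factors.get((chain, cls), 1.0)
        amount = (
            (float(row["area"]) / area_is)
            * is_spec.amount_ug
            / rf
            / ctx.culture_volume_mL
            / ctx.od600
        )
        index.append((chain, cls))
        values.append(amount)
    amounts = pd.Series(
        values,
        index=pd.MultiIndex.from_tuples(index or [], names=["chain_length", "isomer_class"]),
        dtype=float,
    )
    return LipidProfile(amounts)


def marginal_distributions(profile: LipidProfile) -> tuple[pd.Series, pd.Series]:
    """Normalized chain-length and isomer-class marginals (each sums to 1)."""
    joint = profile.joint_distribution()
    chain = joint.groupby(level="chain_length").sum()
    isomer = joint.groupby(level="isomer_class").sum()
    isomer = isomer.reindex([c for c in ISOMER_CLASSES if c in isomer.index])
    return chain, isomer


def modal_chain_length(profile: LipidProfile) -> int:
    chain, _ = marginal_distributions(profile)
    return int(chain.idxmax())


def compare_profiles(p: LipidProfile, q: LipidProfile) -> dict:
    """Total-variation distance on the joint, modal-chain shift, isomer deltas.

    modal_chain_shift = mode(q) - mode(p): negative means q is shifted to
    shorter chains.
    """
    jp, jq = p.joint_distribution(), q.joint_distribution()
    support = jp.index.union(jq.index)
    jp = jp.reindex(support, fill_value=0.0)
    jq = jq.reindex(support, fill_value=0.0)
    tv = 0.5 * float((jp - jq).abs().sum())
    _, ip = marginal_distributions(p)
    _, iq = marginal_distributions(q)
    classes = list(ISOMER_CLASSES)
    deltas = {
        c: float(iq.get(c, 0.0) - ip.get(c, 0.0)) for c in classes
    }
    return {
        "total_variation": tv,
        "modal_chain_shift": modal_chain_length(q) - modal_chain_length(p),
        "isomer_share_deltas": deltas,
    }


def profile_from_series(amounts: dict[tuple[int, str], float]) -> LipidProfile:
    """Build a profile from {(chain_length, isomer_class): amount}."""
    idx = pd.MultiIndex.from_tuples(list(amounts) or [], names=["chain_length", "isomer_class"])
    return LipidProfile(pd.Series(list(amounts.values()), index=idx, dtype=float))
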