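"""Derivation of macronutrient profiles from proximate (wet-chemistry) analysis.

Forage and rumen-content chemistry is reported on the detergent-fiber ladder
(NDF >= ADF >= lignin, all % of dry matter) together with Kjeldahl nitrogen,
fiber-bound nitrogen (ADF-N), ash and, depending on the material, lipids,
sugars, starch and a purine marker of microbial biomass.  This module turns
those raw measurements into the macronutrient quantities used throughout the
package:

* available protein  AP  = 6.25 x (total N - ADF-N)
* hemicellulose      = NDF - ADF
* cellulose          = ADF - lignin
* TNC1               = sugars + starch           (plant material, enzymatic)
* TNC2 + lipids      = 100 - (NDF + AP + ash)    (rumen material, subtraction)
* microbial-N        = 1.1 x purine marker

The subtraction estimate guarantees the compositional closure
``AP + NDF + ash + (TNC2+lipids) = 100`` which the downstream mixture-triangle
geometry relies on.

The 6.25 nitrogen-to-protein factor (proteins average ~16 % N) and the 1.1
yeast-RNA-to-microbial-N factor are definitions, not tunables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "N_TO_PROTEIN",
    "PURINE_TO_MICROBIAL_N",
    "CLIP_TOLERANCE",
    "ValidationError",
    "ProximateRecord",
    "MacronutrientProfile",
    "available_protein",
    "fiber_fractions",
    "tnc2_lipids",
    "tnc1",
    "microbial_n",
    "derive_profile",
    "derive_profiles",
]

logger = logging.getLogger(__name__)

#: Kjeldahl nitrogen to crude protein conversion (1 / 0.16).
N_TO_PROTEIN = 6.25
#: g yeast-RNA equivalents per 100 g dm to microbial-N (% of dm).
PURINE_TO_MICROBIAL_N = 1.1
#: Negative derived values within this many %-points of zero (input rounding)
#: are clipped to 0 with a warning; beyond it the record is rejected.
CLIP_TOLERANCE = 0.5


class ValidationError(ValueError):
    """A proximate record violates a chemical ordering or closure constraint."""


@dataclass(frozen=True)
class ProximateRecord:
    """One sample's measured chemistry, all fractions in % of dry matter.

    ``purine_marker`` is in g yeast-RNA equivalents per 100 g dm (multiply
    mg/g values by 0.1 on ingestion).  ``lipids``, ``sugars`` and ``starch``
    are measured for plant material only; ``purine_marker`` for rumen
    material only.
    """

    sample_id: str
    ash: float
    total_n: float
    adf_n: float
    ndf: float
    adf: float
    lignin: float
    lipids: float | None = None
    sugars: float | None = None
    starch: float | None = None
    purine_marker: float | None = None

    def __post_init__(self) -> None:
        for f in ("ash", "total_n", "adf_n", "ndf", "adf", "lignin"):
            v = getattr(self, f)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {f}={v} outside [0, 100]"
                )
        if not self.ndf >= self.adf >= self.lignin:
            raise ValidationError(
                f"sample {self.sample_id!r}: fiber ladder violated "
                f"(ndf={self.ndf}, adf={self.adf}, lignin={self.lignin})"
            )
        if self.adf_n > self.total_n:
            raise ValidationError(
                f"sample {self.sample_id!r}: adf_n={self.adf_n} exceeds "
                f"total_n={self.total_n}"
            )
        if self.purine_marker is not None and self.purine_marker < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative purine_marker"
            )


@dataclass(frozen=True)
class MacronutrientProfile:
    """Derived macronutrient composition of one sample (% of dry matter)."""

    sample_id: str
    source_kind: Literal["rumen", "plant"]
    ap: float
    crude_protein: float
    cellulose: float
    hemicellulose: float
    lignin: float
    ash: float
    tnc2_lipids: float | None = None
    tnc1: float | None = None
    lipids: float | None = None
    microbial_n: float | None = None

    @property
    def fiber(self) -> float:
        """Cellulose + hemicellulose (equals NDF - lignin)."""
        return self.cellulose + self.hemicellulose

    @property
    def ndf(self) -> float:
        return self.cellulose + self.hemicellulose + self.lignin

    @property
    def closure(self) -> float | None:
        """AP + NDF + ash + TNC2+lipids; 100 for valid rumen profiles."""
        if self.tnc2_lipids is None:
            return None
        return self.ap + self.ndf + self.ash + self.tnc2_lipids


def available_protein(total_n: float, adf_n: float) -> float:
    """Available protein: 6.25 x (total N - fiber-bound N), % of dm.

    ADF-bound nitrogen is nutritionally unavailable, so it is subtracted
    from total Kjeldahl N before the protein conversion.
    """
    if adf_n < 0 or total_n < adf_n:
        raise ValidationError(
            f"require total_n >= adf_n >= 0, got total_n={total_n}, adf_n={adf_n}"
        )
    return N_TO_PROTEIN * (total_n - adf_n)


def fiber_fractions(ndf: float, adf: float, lignin: float) -> tuple[float, float]:
    """Split the detergent-fiber ladder: (hemicellulose, cellulose).

    hemicellulose = NDF - ADF, cellulose = ADF - lignin.
    """
    if not ndf >= adf >= lignin >= 0:
        raise ValidationError(
            f"require ndf >= adf >= lignin >= 0, got ({ndf}, {adf}, {lignin})"
        )
    return ndf - adf, adf - lignin


def tnc2_lipids(ndf: float, ap: float, ash: float, *,
                tolerance: float = CLIP_TOLERANCE) -> float:
    """Nonstructural carbohydrates + lipids by subtraction closure.

    TNC2+lipids = 100 - (NDF + AP + ash).  Small negative results (within
    ``tolerance`` %-points, attributable to rounding of the inputs) are
    clipped to 0; larger deficits are a closure violation.
    """
    value = 100.0 - (ndf + ap + ash)
    if value < -tolerance:
        raise ValidationError(
            f"closure violation: NDF + AP + ash = {ndf + ap + ash:.3f} > 100"
        )
    if value < 0.0:
        logger.warning("TNC2+lipids %.3f clipped to 0", value)
        return 0.0
    return value


def tnc1(sugars: float, starch: float) -> float:
    """Nonstructural carbohydrates of plant material: sugars + starch."""
    if sugars < 0 or starch < 0:
        raise ValidationError(f"negative TNC component: ({sugars}, {starch})")
    return sugars + starch


def microbial_n(purine_marker: float) -> float:
    """Microbial nitrogen (% of dm) from the purine marker.

    The marker is measured in g yeast-RNA equivalents per 100 g dm and
    converted with the standard factor 1.1.
    """
    if purine_marker < 0:
        raise ValidationError(f"negative purine marker: {purine_marker}")
    return PURINE_TO_MICROBIAL_N * purine_marker


def derive_profile(rec: ProximateRecord,
                   source_kind: Literal["rumen", "plant"] = "rumen",
                   ) -> MacronutrientProfile:
    """Derive the full macronutrient profile for one record.

    Rumen records take the subtraction route (TNC2+lipids, closure enforced);
    plant records take the enzymatic route (TNC1 = sugars + starch, lipids
    kept separate).
    """
    hemi, cell = fiber_fractions(rec.ndf, rec.adf, rec.lignin)
    ap = available_protein(rec.total_n, rec.adf_n)
    cp = N_TO_PROTEIN * rec.total_n
    common = dict(
        sample_id=rec.sample_id, ap=ap, crude_protein=cp,
        cellulose=cell, hemicellulose=hemi, lignin=rec.lignin, ash=rec.ash,
    )
    if source_kind == "rumen":
        try:
            t2 = tnc2_lipids(rec.ndf, ap, rec.ash)
        except ValidationError as err:
            raise ValidationError(f"sample {rec.sample_id!r}: {err}") from err
        micn = (None if rec.purine_marker is None
                else microbial_n(rec.purine_marker))
        return MacronutrientProfile(source_kind="rumen", tnc2_lipids=t2,
                                    microbial_n=micn, **common)
    if source_kind == "plant":
        t1 = tnc1(rec.sugars or 0.0, rec.starch or 0.0)
        return MacronutrientProfile(source_kind="plant", tnc1=t1,
                                    lipids=rec.lipids, **common)
    raise ValueError(f"unknown source_kind {source_kind!r}")


_REQUIRED_COLS = ("sample_id", "ash", "total_n", "adf_n", "ndf", "adf", "lignin")


def derive_profiles(table: pd.DataFrame,
                    source_kind: Literal["rumen", "plant"] = "rumen",
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised :func:`derive_profile` over a samples table.

    Returns ``(profiles, report)``: one derived row per accepted sample, and
    a machine-readable validation report listing every rejected or clipped
    record with its reason.  Invalid rows are excluded, never silently fixed.
    """
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    rows, issues = [], []
    for idx, row in table.iterrows():
        rec_kwargs = {c: row[c] for c in _REQUIRED_COLS}
        for opt in ("lipids", "sugars", "starch", "purine_marker"):
            if opt in table.columns and pd.notna(row[opt]):
                rec_kwargs[opt] = float(row[opt])
        rec_kwargs["sample_id"] = str(rec_kwargs["sample_id"])
        try:
            rec = ProximateRecord(**rec_kwargs)
            prof = derive_profile(rec, source_kind=source_kind)
        except ValidationError as err:
            issues.append({"row": idx, "sample_id": str(row["sample_id"]),
                           "status": "rejected", "reason": str(err)})
            continue
        out = {f.name: getattr(prof, f.name) for f in fields(prof)}
        out["fiber"] = prof.fiber
        out["ndf"] = prof.ndf
        rows.append(out)
    profiles = pd.DataFrame(rows)
    report = pd.DataFrame(issues, columns=["row", "sample_id", "status", "reason"])
    return profiles, report
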