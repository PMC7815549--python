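"""Scoring of the 12-item Type D proxy scale and trait transformations.

The proxy measures the two pillars of Type D (distressed) personality with
six negative-affectivity (NA) and six social-inhibition (SI) items, each
rated 0 (never) / 1 (sometimes) / 2 (often), so subscale sums range 0-12.
A person is classified Type D when both subscales reach the cut-off
(default 3).  The continuous Type D measure is the product NA x SI.

Missing data follow a two-step rule: within the chosen survey wave, up to
two missing items per subscale are imputed from the individual's earlier
waves; any still-missing items (at most two) are replaced by the person
mean of the observed items of that subscale; three or more missing items
leave the subscale missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_ITEMS = 6  # items per subscale

#: Canonical item codes, NA then SI, in instrument order.
NA_ITEM_CODES = ["na103", "na112", "na50", "na45", "na115", "na87"]
SI_ITEM_CODES = ["si75", "si67", "si69", "si42", "si111", "si48"]


@dataclass
class ItemResponseWave:
    """One individual's item responses in one survey wave.

    ``na_items``/``si_items`` are length-6 lists of 0/1/2 or None.
    """

    individual_id: str
    wave: int
    na_items: list
    si_items: list
    age_at_survey: float | None = None
    sex: str | None = None

    def n_complete(self) -> int:
        return sum(v is not None for v in self.na_items + self.si_items)


@dataclass
class PhenotypeRecord:
    individual_id: str
    na: float | None
    si: float | None
    naxsi: float | None
    type_d: str  # "yes" / "no" / "missing"
    age: float | None
    sex: str | None


def _check_item(v) -> None:
    if v is not None and v not in (0, 1, 2):
        raise ValueError(f"item value must be 0, 1, 2 or missing; got {v!r}")


def score_subscale(items) -> float | None:
    """Sum a 6-item subscale, person-mean-imputing up to two missing items.

    Returns None when three or more items are missing.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    for v in items:
        _check_item(v)
    observed = [v for v in items if v is not None]
    n_missing = N_ITEMS - len(observed)
    if n_missing >= 3:
        return None
    if n_missing == 0:
        return float(sum(observed))
    person_mean = sum(observed) / len(observed)
    return float(sum(observed) + n_missing * person_mean)


def select_wave(
    waves: list[ItemResponseWave],
    relatives_with_data: dict[int, int] | None = None,
) -> ItemResponseWave | None:
    """Choose the survey wave to score.

    Preference order: most complete of the 12 proxy items, then most other
    pedigree relatives with data in that wave, then the earliest wave.
    Returns None when every wave is empty.
    """
    if not waves:
        return None
    relatives_with_data = relatives_with_data or {}
    best = max(
        waves,
        key=lambda w: (
            w.n_complete(),
            relatives_with_data.get(w.wave, 0),
            -w.wave,
        ),
    )
    if best.n_complete() == 0:
        return None
    return best


def cross_wave_impute(
    target: ItemResponseWave, history: list[ItemResponseWave]
) -> ItemResponseWave:
    """Fill missing items in ``target`` from the individual's earlier waves.

    For each missing slot the most recent *previous* wave holding that item
    donates its value.  Items still missing afterwards are left for the
    person-mean rule in :func:`score_subscale`.
    """
    donors = sorted(
        (w for w in history if w.wave < target.wave),
        key=lambda w: -w.wave,
    )

    def fill(slot_name: str) -> list:
        slots = list(getattr(target, slot_name))
        for k, v in enumerate(slots):
            if v is None:
                for donor in donors:
                    dv = getattr(donor, slot_name)[k]
                    if dv is not None:
                        slots[k] = dv
                        break
        return slots

    return ItemResponseWave(
        individual_id=target.individual_id,
        wave=target.wave,
        na_items=fill("na_items"),
        si_items=fill("si_items"),
        age_at_survey=target.age_at_survey,
        sex=target.sex,
    )


def classify_type_d(na, si, cutoff: int = 3) -> str:
    """Dichotomous Type D: both subscales at or above the cut-off.

    With one subscale missing, a below-cut-off value on the other decides
    "no" (both must reach the cut-off); an at-or-above value leaves the
    classification undecidable ("missing").
    """
    for v in (na, si):
        if v is not None and v < 0:
            raise ValueError(f"subscale scores cannot be negative: {v}")
    if na is None and si is None:
        return "missing"
    if na is None or si is None:
        present = si if na is None else na
        return "no" if present < cutoff else "missing"
    return "yes" if (na >= cutoff and si >= cutoff) else "no"


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 3/8).

    Maps values to standard-normal quantiles of (rank - 3/8) / (n + 1/4),
    with tied ranks averaged; NaN entries stay NaN.  A constant input has no
    rank information and maps to all zeros (with a warning).
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    obs = values[mask]
    if obs.size < 2:
        raise ValueError("inverse normal transform needs at least 2 observed values")
    if np.ptp(obs) == 0:
        warnings.warn("constant input to inverse normal transform; returning zeros")
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.375) / (obs.size + 0.25))
    return out


def score_individual(
    waves: list[ItemResponseWave],
    relatives_with_data: dict[int, int] | None = None,
    cutoff: int = 3,
) -> PhenotypeRecord:
    """Full per-person pipeline: wave selection, cross-wave fill, scoring."""
    iid = waves[0].individual_id if waves else "?"
    chosen = select_wave(waves, relatives_with_data)
    if chosen is None:
        return PhenotypeRecord(iid, None, None, None, "missing", None, None)
    filled = cross_wave_impute(chosen, [w for w in waves if w is not chosen])
    na = score_subscale(filled.na_items)
    si = score_subscale(filled.si_items)
    naxsi = na * si if (na is not None and si is not None) else None
    return PhenotypeRecord(
        individual_id=filled.individual_id,
        na=na,
        si=si,
        naxsi=naxsi,
        type_d=classify_type_d(na, si, cutoff),
        age=filled.age_at_survey,
        sex=filled.sex,
    )


# -- long-format item table I/O -------------------------------------------------


def waves_from_long(df: pd.DataFrame) -> dict[str, list[ItemResponseWave]]:
    """Parse a long item table (individual_id, wave, item_code, value [, age, sex]).

    Unknown item codes are rejected; absent items are missing.
    """
    code_slot = {c: ("na_items", k) for k, c in enumerate(NA_ITEM_CODES)}
    code_slot.update({c: ("si_items", k) for k, c in enumerate(SI_ITEM_CODES)})
    out: dict[str, list[ItemResponseWave]] = {}
    for (iid, wave), sub in df.groupby(["individual_id", "wave"], sort=True):
        w = ItemResponseWave(
            individual_id=str(iid),
            wave=int(wave),
            na_items=[None] * N_ITEMS,
            si_items=[None] * N_ITEMS,
        )
        for row in sub.itertuples(index=False):
            code = str(row.item_code)
            if code not in code_slot:
                raise ValueError(f"unknown item code {code!r}")
            if not pd.isna(row.value):
                slot, k = code_slot[code]
                getattr(w, slot)[k] = int(row.value)
        if "age_at_survey" in sub.columns and sub["age_at_survey"].notna().any():
            w.age_at_survey = float(sub["age_at_survey"].dropna().iloc[0])
        if "sex" in sub.columns and sub["sex"].notna().any():
            w.sex = str(sub["sex"].dropna().iloc[0])
        out.setdefault(str(iid), []).append(w)
    return out


def phenotypes_to_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "na": r.na,
                "si": r.si,
                "naxsi": r.naxsi,
                "type_d": r.type_d,
                "age": r.age,
                "sex": r.sex,
            }
            for r in records
        ]
    )
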