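"""Domain records for collagen isotope data and study configuration.

The measurement unit throughout is per-mil (‰): δ13C relative to V-PDB and
δ15N relative to AIR. Elemental concentrations are fractions in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "TRACERS",
    "TRACER_ELEMENT",
    "ConsumerRecord",
    "SourceSpec",
    "QCCriteria",
    "AgeCategoryScheme",
    "StudyDataset",
    "qc_filter",
    "suess_correct",
    "assign_age_category",
    "default_age_scheme",
]

#: Canonical tracer order used everywhere.
TRACERS: tuple[str, str] = ("d13c", "d15n")

#: Which elemental concentration weights each tracer (carbon routes δ13C,
#: nitrogen routes δ15N).
TRACER_ELEMENT: dict[str, str] = {"d13c": "C", "d15n": "N"}


class ValidationError(ValueError):
    """A record or configuration violates a structural invariant."""


@dataclass(frozen=True)
class ConsumerRecord:
    """One isotopic measurement of one tissue of one individual.

    Bone carries a single measurement per individual; dentine carries one
    record per sequential slice, ordered crown → apex by ``slice_index``.
    """

    individual_id: str
    subgroup: str
    tissue: str  # "bone" | "dentine"
    d13c: float
    d15n: float
    pct_c: Optional[float] = None
    pct_n: Optional[float] = None
    cn_ratio: Optional[float] = None
    collagen_yield: Optional[float] = None
    slice_index: Optional[int] = None
    site: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in ("bone", "dentine"):
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.tissue == "bone" and self.slice_index is not None:
            raise ValidationError(
                f"bone record {self.individual_id!r} must not carry slice_index"
            )
        if self.tissue == "dentine" and self.slice_index is None:
            raise ValidationError(
                f"dentine record {self.individual_id!r} requires slice_index"
            )
        if self.slice_index is not None and self.slice_index < 0:
            raise ValidationError("slice_index must be non-negative")


@dataclass(frozen=True)
class SourceSpec:
    """A food-source group: tracer samples, TEFs and elemental concentrations.

    Parameters
    ----------
    name : str
        Source-group label, e.g. ``"marine_fish"``.
    samples : mapping tracer -> array
        Measured tracer values (‰) of the source's reference specimens.
    tef : mapping tracer -> (mean, sd)
        Trophic enrichment factor λ per tracer, in ‰. The sd quantifies TEF
        uncertainty and must be ≥ 0.
    conc : mapping element -> fraction
        Elemental concentration c for "C" and "N", fractions in (0, 1].
    """

    name: str
    samples: Mapping[str, np.ndarray]
    tef: Mapping[str, tuple[float, float]]
    conc: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "samples",
            {t: np.asarray(v, dtype=float) for t, v in dict(self.samples).items()},
        )
        for e, c in self.conc.items():
            if not (0.0 < c <= 1.0):
                raise ValidationError(
                    f"source {self.name!r}: concentration {e}={c} outside (0, 1]"
                )
        for t, (_, sd) in self.tef.items():
            if sd < 0:
                raise ValidationError(f"source {self.name!r}: TEF sd < 0 for {t}")

    def n_samples(self, tracer: str) -> int:
        return int(np.asarray(self.samples.get(tracer, ())).size)

    def adjusted_mean(self, tracer: str) -> float:
        """Sample mean plus TEF mean — the naive diet-adjusted source value."""
        return float(np.mean(self.samples[tracer])) + float(self.tef[tracer][0])


@dataclass(frozen=True)
class QCCriteria:
    """Collagen quality thresholds.

    Defaults follow the conventional archaeological-collagen criteria:
    carbon and nitrogen content strictly above 13% and 5% and an atomic C/N
    ratio inside [2.9, 3.6]. The collagen-yield check (> min_yield mg/g)
    applies only when ``min_yield`` is configured and the record carries a
    yield; dentine slices typically do not.
    """

    min_pct_c: float = 13.0
    min_pct_n: float = 5.0
    cn_low: float = 2.9
    cn_high: float = 3.6
    min_yield: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.cn_low < self.cn_high):
            raise ValidationError("cn_low must be < cn_high")
        for v in (self.min_pct_c, self.min_pct_n, self.cn_low, self.cn_high):
            if v <= 0:
                raise ValidationError("QC thresholds must be positive")


def _as_finite_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return math.nan
    return x


def qc_filter(
    records: Sequence[ConsumerRecord], criteria: QCCriteria = QCCriteria()
) -> tuple[list[ConsumerRecord], list[tuple[ConsumerRecord, str]]]:
    """Partition records into QC-passing and rejected-with-reason.

    Never raises on bad field values: a missing QC field rejects with
    ``"missing_field"``, a non-numeric one with ``"non_numeric"``. The
    returned lists are disjoint and jointly exhaust the input.
    """
    kept: list[ConsumerRecord] = []
    rejected: list[tuple[ConsumerRecord, str]] = []
    for rec in records:
        pct_c = _as_finite_float(rec.pct_c)
        pct_n = _as_finite_float(rec.pct_n)
        cn = _as_finite_float(rec.cn_ratio)
        if pct_c is None or pct_n is None or cn is None:
            rejected.append((rec, "missing_field"))
            continue
        if any(math.isnan(v) for v in (pct_c, pct_n, cn)):
            rejected.append((rec, "non_numeric"))
            continue
        if not pct_c > criteria.min_pct_c:
            rejected.append((rec, "pct_c_too_low"))
            continue
        if not pct_n > criteria.min_pct_n:
            rejected.append((rec, "pct_n_too_low"))
            continue
        if not (criteria.cn_low <= cn <= criteria.cn_high):
            rejected.append((rec, "cn_out_of_range"))
            continue
        if criteria.min_yield is not None and rec.collagen_yield is not None:
            y = _as_finite_float(rec.collagen_yield)
            if math.isnan(y):
                rejected.append((rec, "non_numeric"))
                continue
            if not y > criteria.min_yield:
                rejected.append((rec, "yield_too_low"))
                continue
        kept.append(rec)
    return kept, rejected


def suess_correct(d13c_modern: float, shift: float = 2.0) -> float:
    """Shift a modern δ13C value to pre-industrial baseline.

    Atmospheric δ13C has been depleted by fossil-fuel CO2 (the Suess
    effect); modern plant reference values must be raised (+2‰ for 2010-era
    material) before comparison with archaeological collagen.
    """
    if not (math.isfinite(d13c_modern) and math.isfinite(shift)):
        raise ValidationError("suess_correct requires finite inputs")
    return d13c_modern + shift


@dataclass(frozen=True)
class AgeCategoryScheme:
    """Maps dentine anatomical segments to approximate ages and age categories.

    ``dentine_segments`` maps (tooth_type, segment) to an approximate
    formation-age interval in years; ``categories`` is an ordered list of
    (label, low, high) intervals, contiguous and non-overlapping, each
    half-open [low, high). Records whose assigned age midpoint falls below
    ``exclusion_age`` are dropped from model input (breastfeeding bias).
    """

    dentine_segments: Mapping[tuple[str, str], tuple[float, float]]
    categories: Sequence[tuple[str, float, float]]
    exclusion_age: float = 5.0

    def __post_init__(self) -> None:
        if self.exclusion_age < 0:
            raise ValidationError("exclusion_age must be >= 0")
        cats = list(self.categories)
        for (_, lo, hi) in cats:
            if not lo < hi:
                raise ValidationError("age category interval must have low < high")
        for (_, _, hi_prev), (_, lo, _) in zip(cats, cats[1:]):
            if hi_prev != lo:
                raise ValidationError("age categories must be contiguous")

    def category_of_age(self, age: float) -> str:
        for label, lo, hi in self.categories:
            if lo <= age < hi:
                return label
        raise KeyError(f"age {age} outside all configured categories")

    def excluded_categories(self) -> set[str]:
        """Labels of categories entirely below the exclusion age."""
        return {
            label for label, lo, hi in self.categories if hi <= self.exclusion_age
        }


def default_age_scheme() -> AgeCategoryScheme:
    """Dentine-formation age grid for molars and second premolar.

    Segment bounds are approximate formation ages (years); where the
    anatomical literature prints alternatives ("9/10"), the first value is
    used. Categories: under-5 (excluded by default), 5–9, 9–15, 15–18 and
    adults.
    """
    seg = {
        ("first_molar", "cusp_to_crown_completed"): (0.0, 3.0),
        ("first_molar", "crown_completed_to_bifurcation"): (3.0, 5.0),
        ("first_molar", "bifurcation_to_root_half"): (5.0, 7.0),
        ("first_molar", "root_half_to_root_completed"): (7.0, 9.0),
        ("second_molar", "cusp_to_crown_completed"): (2.0, 8.0),
        ("second_molar", "crown_completed_to_bifurcation"): (8.0, 9.0),
        ("second_molar", "bifurcation_to_root_half"): (9.0, 11.0),
        ("second_molar", "root_half_to_root_completed"): (11.0, 15.0),
        ("third_molar", "cusp_to_crown_completed"): (9.0, 14.0),
        ("third_molar", "crown_completed_to_bifurcation"): (14.0, 17.0),
        ("third_molar", "bifurcation_to_root_half"): (17.0, 19.0),
        ("second_premolar", "cusp_to_crown_completed"): (3.5, 8.5),
        ("second_premolar", "crown_completed_to_bifurcation"): (8.5, 10.5),
        ("second_premolar", "bifurcation_to_root_half"): (10.5, 13.5),
    }
    cats = [
        ("under 5 years", 0.0, 5.0),
        ("5-9 years", 5.0, 9.0),
        ("9-15 years", 9.0, 15.0),
        ("15-18 years", 15.0, 18.0),
        ("adults", 18.0, math.inf),
    ]
    return AgeCategoryScheme(dentine_segments=seg, categories=cats)


def assign_age_category(
    tooth_type: str, segment: str, scheme: AgeCategoryScheme
) -> str:
    """Age category containing the midpoint of a dentine segment's age range.

    Deterministic surrogate for anatomical age-alignment: each slice is
    assigned the category of its segment's midpoint age.
    """
    key = (tooth_type, segment)
    try:
        lo, hi = scheme.dentine_segments[key]
    except KeyError:
        raise KeyError(
            f"unknown (tooth_type, segment) pair {key!r}"
        ) from None
    return scheme.category_of_age((lo + hi) / 2.0)


@dataclass
class StudyDataset:
    """Validated model input: QC-passing consumers plus source groups.

    Attributes
    ----------
    consumers : list of ConsumerRecord
    sources : list of SourceSpec
    tracers : ordered tracer labels present in every source
    subgroups : ordered subgroup labels fitted by the model
    qc_rejected : records dropped by quality filtering, with reasons
    excluded : records dropped by the under-age exclusion
    """

    consumers: list[ConsumerRecord]
    sources: list[SourceSpec]
    tracers: tuple[str, ...] = TRACERS
    subgroups: tuple[str, ...] = ()
    qc_rejected: list[tuple[ConsumerRecord, str]] = field(default_factory=list)
    excluded: list[ConsumerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subgroups:
            seen: list[str] = []
            for r in self.consumers:
                if r.subgroup not in seen:
                    seen.append(r.subgroup)
            self.subgroups = tuple(seen)
        labels = set(self.subgroups)
        for r in self.consumers:
            if r.subgroup not in labels:
                raise ValidationError(
                    f"consumer {r.individual_id!r} subgroup {r.subgroup!r} "
                    "not in configured subgroups"
                )
        for s in self.sources:
            for t in self.tracers:
                if t not in s.samples:
                    raise ValidationError(
                        f"source {s.name!r} lacks tracer {t!r} samples"
                    )

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources)

    def counts(self):
        """Per-subgroup record counts by tissue (a DataFrame)."""
        import pandas as pd

        rows = []
        for g in self.subgroups:
            recs = [r for r in self.consumers if r.subgroup == g]
            bone = sum(1 for r in recs if r.tissue == "bone")
            dent = sum(1 for r in recs if r.tissue == "dentine")
            teeth = len({r.individual_id for r in recs if r.tissue == "dentine"})
            rows.append(
                {"subgroup": g, "bone": bone, "dentine_slices": dent, "teeth": teeth}
            )
        return pd.DataFrame(rows)

    def individuals(self) -> dict[tuple[str, str], list[ConsumerRecord]]:
        """Group records by (individual_id, tissue), slices ordered."""
        out: dict[tuple[str, str], list[ConsumerRecord]] = {}
        for r in self.consumers:
            out.setdefault((r.individual_id, r.tissue), []).append(r)
        for key, recs in out.items():
            if key[1] == "dentine":
                recs.sort(key=lambda r: r.slice_index)
        return out


def _replace_subgroup(rec: ConsumerRecord, subgroup: str) -> ConsumerRecord:
    return replace(rec, subgroup=subgroup)
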