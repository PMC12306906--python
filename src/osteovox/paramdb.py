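"""Anatomical-morphological parameter database.

Houses the machine-readable transcription of the published parameter tables
driving stochastic bone-segment phantom generation: the segment registry
(one row per unique basic phantom segment, 289 in total over the six
reference ages), trabecular micro-architecture (BV/TV, Tb.Th, Tb.Sp with
population SDs), intra-specimen coefficients of variation (CV_IS), tissue
densities, and segment dimensions where size data exist.

The six reference ages are newborn (``0-Y``), 1, 5, 10 and 15 years and
adult.  Sex-specific rows exist only for 15-Y and adult segments; younger
ages are unisex, reflecting the negligible sex differences in pre-pubertal
skeletal size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (MissingDimensionsError, NotModeledAtAgeError,
                     OsteovoxError, UnknownSegmentError)

#: Reference-age labels in chronological order.
AGES: tuple[str, ...] = ("0-Y", "1-Y", "5-Y", "10-Y", "15-Y", "adult")

#: Ages at which sex-specific segment rows may exist.
SEXED_AGES: frozenset[str] = frozenset({"15-Y", "adult"})

_SEX_ALIASES = {"male": "m", "female": "f", "m": "m", "f": "f",
                "u": "u", "unisex": "u", None: None}

#: shape kinds collapsed to the census families used in reporting
SHAPE_FAMILY = {"elliptic-cylinder": "cylinder", "truncated-cone": "cone"}


def normalize_age(age: str) -> str:
    a = str(age).strip()
    aliases = {"0": "0-Y", "1": "1-Y", "5": "5-Y", "10": "10-Y", "15": "15-Y",
               "newborn": "0-Y", "adult": "adult", "adults": "adult"}
    a = aliases.get(a.lower(), a)
    if a not in AGES:
        raise OsteovoxError(f"unknown reference age {age!r}; expected one of {AGES}")
    return a


def normalize_sex(sex: str | None) -> str | None:
    try:
        return _SEX_ALIASES[sex if sex is None else str(sex).lower()]
    except KeyError:
        raise OsteovoxError(f"unknown sex {sex!r}") from None


@dataclass(frozen=True)
class MicroParams:
    """Trabecular micro-architecture of one segment at one age.

    ``bvtv`` is the mineralised fraction of the spongiosa (0-1), ``tbth``
    the rod thickness and ``tbsp`` the inter-trabecular distance, both in
    mm; SDs are inter-individual (population) spreads.  ``cvis_*`` are the
    intra-specimen coefficients of variation (percent) that set the range
    of the stochastic lattice deformation.
    """

    bvtv_mean: float
    bvtv_sd: float
    tbth_mean: float
    tbth_sd: float
    tbsp_mean: float
    tbsp_sd: float
    cvis_tbth: float
    cvis_tbsp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.bvtv_mean < 1.0:
            raise OsteovoxError(f"BV/TV must be in (0,1), got {self.bvtv_mean}")
        if self.tbth_mean <= 0 or self.tbsp_mean <= 0:
            raise OsteovoxError("Tb.Th and Tb.Sp must be positive")
        for sd in (self.bvtv_sd, self.tbth_sd, self.tbsp_sd,
                   self.cvis_tbth, self.cvis_tbsp):
            if sd < 0:
                raise OsteovoxError("SDs and CVs must be non-negative")


@dataclass(frozen=True)
class Dimension:
    """A named linear dimension (mm) with population mean and SD.

    ``role`` maps the anatomical symbol onto the geometric primitive's
    parameter slot (box a/b/c, cylinder d1/d2/h, cone d_base/d_top/h,
    ellipsoid d1/d2/d3, prism a/b/h).
    """

    name: str
    role: str
    mean: float
    sd: float


@dataclass(frozen=True)
class SegmentSpec:
    """Full parameterisation of one basic phantom segment at one age."""

    site: str
    part: str
    age: str
    sex: str
    shape: str
    micro: MicroParams
    multiplicity: int
    am_fraction_scale: float
    modeled_ages: frozenset[str]
    dims: tuple[Dimension, ...] = ()
    ctth_mean: float | None = None
    ctth_sd: float | None = None
    cortical_faces: tuple[str, ...] = ()

    @property
    def has_dims(self) -> bool:
        return bool(self.dims) and self.ctth_mean is not None

    def dim(self, role: str) -> Dimension:
        for d in self.dims:
            if d.role == role:
                return d
        raise MissingDimensionsError(
            f"{self.site}/{self.part} ({self.age}, {self.sex}) has no dimension "
            f"with role {role!r}")


@dataclass(frozen=True)
class DensityTable:
    """Mineralised-bone and marrow densities (g/cm^3) per reference age."""

    mineral_density: Mapping[str, float]
    marrow_density: Mapping[str, float]


@dataclass(frozen=True)
class StudyRecord:
    """One published study entering the evidence pooling.

    ``age_range_flag`` is true when individual ages were unavailable and the
    study group's upper age limit exceeded 50 (female) / 59 (male) years, or
    subjects were reported simply as "adults" — the condition that triggers
    the down-weighting factor W_A = 0.75 for micro-parameters.
    """

    n_subjects: int
    mean: float
    sd: float
    age_range_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise OsteovoxError("n_subjects must be >= 1")
        if self.sd < 0:
            raise OsteovoxError("sd must be >= 0")


@dataclass(frozen=True)
class PooledEstimate:
    mean: float
    sd: float
    range: tuple[float, float]


def study_weight(rec: StudyRecord, context: str = "micro") -> float:
    """Confidence weight of one study.

    W_N = min(1, N/25) accounts for the number of subjects.  For
    micro-parameters an additional W_A = 0.75 applies when the study's age
    range extends beyond the reference-adult window (``age_range_flag``);
    for bone sizes only W_N is considered, since dimensions are stable
    through adulthood.
    """
    if context not in ("micro", "size"):
        raise OsteovoxError(f"context must be 'micro' or 'size', got {context!r}")
    w_n = 1.0 if rec.n_subjects >= 25 else rec.n_subjects / 25.0
    if context == "micro" and rec.age_range_flag:
        return w_n * 0.75
    return w_n


def pool_studies(records: Sequence[StudyRecord], context: str = "micro",
                 stated_range: tuple[float, float] | None = None) -> PooledEstimate:
    """Weight-average several studies of the same quantity.

    The pooled mean is the weighted mean of study means, the pooled SD the
    weighted mean of study SDs (not a variance pool: the SDs describe
    population spread, not estimation error), and the range is the author-
    stated one when supplied, otherwise mean +/- 2 SD.
    """
    if not records:
        raise OsteovoxError("pool_studies requires at least one record")
    weights = [study_weight(r, context) for r in records]
    wsum = sum(weights)
    mean = sum(w * r.mean for w, r in zip(weights, records)) / wsum
    sd = sum(w * r.sd for w, r in zip(weights, records)) / wsum
    rng = stated_range if stated_range is not None else (mean - 2 * sd, mean + 2 * sd)
    return PooledEstimate(mean, sd, rng)


def cvis_group_average(groups: Iterable[float]) -> int:
    """Arithmetic mean of group CVs, rounded half-up to integer percent.

    Used to assign the "other bones" intra-specimen CV from the bone groups
    with direct measurements.
    """
    values = list(groups)
    if not values:
        raise OsteovoxError("cvis_group_average requires at least one value")
    return int(math.floor(sum(values) / len(values) + 0.5))


# --------------------------------------------------------------------------
# database

_SITE_CV_GROUP = {
    "pelvis": "pelvic",
    "vertebrae_c": "vertebrae", "vertebrae_t": "vertebrae",
    "vertebrae_l": "vertebrae", "sacrum": "vertebrae",
    "skull": "skull",
}

#: default covered faces per shape kind: plate-like boxes carry cortex on the
#: two large faces, cylindrical/conical segments on the lateral surface.
_DEFAULT_FACES = {
    "box": ("z-", "z+"),
    "cylinder": ("lateral",),
    "elliptic-cylinder": ("lateral",),
    "truncated-cone": ("lateral",),
    "prism": ("lateral",),
    "ellipsoid": ("all",),
}


class ParameterDatabase:
    """In-memory view of the packaged parameter tables with lookups."""

    def __init__(self, registry: pd.DataFrame, micro: pd.DataFrame,
                 cvis: pd.DataFrame, densities: pd.DataFrame,
                 dimensions: pd.DataFrame):
        self.registry = registry
        self.micro = micro
        self.cvis = cvis
        self._densities = densities
        self.dimensions = dimensions
        self._validate()

    # -- loading ----------------------------------------------------------
    @classmethod
    def load_packaged(cls) -> "ParameterDatabase":
        root = resources.files("osteovox") / "data"
        read = lambda name: pd.read_csv(root / name)  # noqa: E731
        return cls(read("registry.csv"), read("microstructure.csv"),
                   read("cvis.csv"), read("densities.csv"), read("dimensions.csv"))

    def _validate(self) -> None:
        key = ["site", "part", "age", "sex"]
        if self.registry.duplicated(key).any():
            raise OsteovoxError("duplicate registry rows")
        mk = self.micro.set_index(["micro_site", "micro_group", "age"]).index
        want = self.registry.set_index(["micro_site", "micro_group", "age"]).index
        missing = set(want) - set(mk)
        if missing:
            raise OsteovoxError(f"registry rows without micro-parameters: {sorted(missing)[:5]}")
        # micro-parameter invariants hold for every stored row
        for _, r in self.micro.iterrows():
            MicroParams(r.bvtv_mean, r.bvtv_sd, r.tbth_mean, r.tbth_sd,
                        r.tbsp_mean, r.tbsp_sd, 0.0, 0.0)

    def load_s15(self, path) -> None:
        """Merge a CSV export of a per-segment size workbook.

        Expected columns: site, part, age, sex, param, role, mean, sd.
        Rows replace packaged dimensions for matching segments.
        """
        extra = pd.read_csv(path)
        need = {"site", "part", "age", "sex", "param", "role", "mean", "sd"}
        if not need.issubset(extra.columns):
            raise OsteovoxError(f"size table must have columns {sorted(need)}")
        key = ["site", "part", "age", "sex"]
        drop = self.dimensions.set_index(key).index.isin(extra.set_index(key).index)
        self.dimensions = pd.concat(
            [self.dimensions[~drop], extra], ignore_index=True)

    # -- density ----------------------------------------------------------
    @property
    def densities(self) -> DensityTable:
        d = self._densities.set_index("age")
        return DensityTable(mineral_density=d["mineral_density"].to_dict(),
                            marrow_density=d["marrow_density"].to_dict())

    # -- CV_IS ------------------------------------------------------------
    def cvis_for_site(self, site: str) -> tuple[float, float]:
        group = _SITE_CV_GROUP.get(site, "other")
        row = self.cvis[self.cvis.group == group].iloc[0]
        return float(row.tbth_cv), float(row.tbsp_cv)

    def measured_cvis(self, which: str) -> list[float]:
        """CV_IS values (%) of the directly measured bone groups."""
        col = {"tbth": "tbth_cv", "tbsp": "tbsp_cv"}[which]
        return [float(v) for v in self.cvis[self.cvis.measured == 1][col]]

    # -- registry queries --------------------------------------------------
    def get_segment(self, site: str, part: str, age: str,
                    sex: str | None = None) -> SegmentSpec:
        """Resolve one segment at one reference age.

        Unisex rows are served to any sex; 15-Y/adult sex-split segments
        default to the male row when ``sex`` is omitted.  A segment that is
        not modeled at the requested age (dark field in the parameter
        tables: hematopoiesis has ceased there) raises
        :class:`NotModeledAtAgeError`.
        """
        age = normalize_age(age)
        sex = normalize_sex(sex)
        reg = self.registry
        seg = reg[(reg.site == site) & (reg.part == part)]
        if seg.empty:
            raise UnknownSegmentError(f"unknown segment {site}/{part}")
        modeled = frozenset(seg.age)
        at_age = seg[seg.age == age]
        if at_age.empty:
            raise NotModeledAtAgeError(
                f"{site}/{part} is not modeled at {age} (modeled ages: "
                f"{sorted(modeled, key=AGES.index)})")
        if sex in (None, "u"):
            pick = at_age[at_age.sex == "u"]
            if pick.empty:  # sex-split segment queried without sex
                pick = at_age[at_age.sex == "m"]
        else:
            pick = at_age[at_age.sex.isin(["u", sex])]
            # prefer the sex-specific row over a unisex one
            pick = pick.sort_values("sex", key=lambda s: s.ne(sex)).head(1)
        row = pick.iloc[0]

        m = self.micro.set_index(["micro_site", "micro_group", "age"]).loc[
            (row.micro_site, row.micro_group, age)]
        cv_th, cv_sp = self.cvis_for_site(site)
        micro = MicroParams(m.bvtv_mean, m.bvtv_sd, m.tbth_mean, m.tbth_sd,
                            m.tbsp_mean, m.tbsp_sd, cv_th, cv_sp)

        dims_df = self.dimensions
        dd = dims_df[(dims_df.site == site) & (dims_df.part == part)
                     & (dims_df.age == age) & (dims_df.sex == row.sex)]
        dims, ct_mean, ct_sd = [], None, None
        for _, d in dd.iterrows():
            if d.role == "ctth":
                ct_mean, ct_sd = float(d["mean"]), float(d.sd)
            else:
                dims.append(Dimension(d.param, d.role, float(d["mean"]), float(d.sd)))

        return SegmentSpec(
            site=site, part=part, age=age, sex=row.sex, shape=row["shape"],
            micro=micro, multiplicity=int(row.multiplicity),
            am_fraction_scale=float(row.am_fraction_scale),
            modeled_ages=modeled, dims=tuple(dims),
            ctth_mean=ct_mean, ctth_sd=ct_sd,
            cortical_faces=_DEFAULT_FACES[row["shape"]])

    def count_bps(self, ages: Iterable[str]) -> int:
        """Number of unique basic phantom segments over the requested ages.

        Sex-specific variants count separately; dark-field (not-modeled)
        combinations are simply absent from the registry.
        """
        wanted = {normalize_age(a) for a in ages}
        if not wanted:
            return 0
        return int(self.registry.age.isin(wanted).sum())

    def shape_census(self, ages: Iterable[str] | None = None) -> dict[str, float]:
        """Percentage of unique segments per shape family over ``ages``."""
        reg = self.registry
        if ages is not None:
            wanted = {normalize_age(a) for a in ages}
            reg = reg[reg.age.isin(wanted)]
        if reg.empty:
            return {}
        if reg["shape"].isna().any():
            raise OsteovoxError("segments without a shape assignment")
        fams = reg["shape"].map(lambda s: SHAPE_FAMILY.get(s, s))
        counts = fams.value_counts()
        return {k: 100.0 * v / len(reg) for k, v in counts.items()}

    def segments_at(self, age: str, site: str | None = None,
                    sex: str | None = None) -> list[SegmentSpec]:
        """All segments modeled at one age (optionally one site/sex)."""
        age = normalize_age(age)
        sex = normalize_sex(sex)
        reg = self.registry[self.registry.age == age]
        if site is not None:
            reg = reg[reg.site == site]
        if sex is not None:
            reg = reg[reg.sex.isin(["u", sex])]
        return [self.get_segment(r.site, r.part, age, None if r.sex == "u" else r.sex)
                for r in reg.itertuples()]


@lru_cache(maxsize=1)
def default_db() -> ParameterDatabase:
    """The packaged database (loaded once per process)."""
    return ParameterDatabase.load_packaged()
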