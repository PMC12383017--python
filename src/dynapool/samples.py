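"""Sample records, sample-table IO and summary statistics.

The unit conventions used throughout the package are fixed here: body
length in millimetres, body weight in grams, age in whole years (otolith
annulus counts).  Sex is one of ``female`` / ``male`` / ``unknown``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataFormatError, InsufficientDataError

SEXES = ("female", "male", "unknown")

#: Required columns of the sample-table dialect (header row, "." decimal).
REQUIRED_COLUMNS = ("species", "sex", "age", "length_mm", "weight_g")
OPTIONAL_COLUMNS = ("site", "season")

_SEX_CODES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "u": "unknown", "unknown": "unknown", "": "unknown",
}


@dataclass(frozen=True)
class FishSample:
    """One measured individual."""

    species_id: str
    sex: str
    age: int
    body_length: float  # mm
    body_weight: float  # g
    site_id: str | None = None
    season: str | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.body_length > 0:
            raise ValueError(f"body_length must be > 0, got {self.body_length}")
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if self.age < 0 or int(self.age) != self.age:
            raise ValueError(f"age must be a non-negative integer, got {self.age}")


@dataclass
class SampleSet:
    """An ordered collection of samples from a single species."""

    samples: list[FishSample]
    species_id: str
    rejected: list[dict] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self):
        if not self.samples:
            raise InsufficientDataError("SampleSet must be non-empty")
        for s in self.samples:
            if s.species_id != self.species_id:
                raise ValueError(
                    f"sample species {s.species_id!r} != set species {self.species_id!r}"
                )

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def lengths(self) -> list[float]:
        return [s.body_length for s in self.samples]

    @property
    def weights(self) -> list[float]:
        return [s.body_weight for s in self.samples]

    @property
    def ages(self) -> list[int]:
        return [s.age for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [s.species_id for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "age": self.ages,
                "length_mm": self.lengths,
                "weight_g": self.weights,
                "site": [s.site_id for s in self.samples],
                "season": [s.season for s in self.samples],
            }
        )


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species assessment configuration.

    ``temperature_c`` is the annual mean water temperature of the habitat,
    required by Pauly's natural-mortality formula; ``length_at_first_capture``
    is the knife-edge gear-selection length Lc in mm.  Neither is measurable
    from the sample table itself, so both are explicit inputs.
    """

    species_id: str
    temperature_c: float | None = None
    length_at_first_capture: float | None = None
    alpha: float = 0.05

    def __post_init__(self):
        if self.temperature_c is not None and not self.temperature_c > 0:
            raise ValueError("temperature_c must be > 0 when supplied")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with an interval, or an interval alone.

    When only a confidence interval is published, the midpoint stands in
    for the point estimate (``value``).
    """

    lower: float
    upper: float
    point: float | None = None
    confidence: float = 0.95

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) > upper ({self.upper})")

    @property
    def value(self) -> float:
        if self.point is not None:
            return self.point
        return 0.5 * (self.lower + self.upper)


def point_estimate(iv: IntervalEstimate) -> float:
    """Point value of an interval estimate (midpoint when no point given)."""
    return iv.value


def _parse_sex(raw) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unknown"
    key = str(raw).strip().lower()
    if key in _SEX_CODES:
        return _SEX_CODES[key]
    raise ValueError(f"unrecognised sex code {raw!r}")


def read_samples(path, *, delimiter: str = ",", species_id: str | None = None) -> SampleSet:
    """Read a delimited sample table into a :class:`SampleSet`.

    Rows violating the sample invariants (non-positive length/weight,
    negative or non-integer age, bad sex code) are rejected individually;
    a per-row report is attached to the returned set as ``.rejected``.

    Raises :class:`DataFormatError` if a required column is missing, and
    :class:`InsufficientDataError` if no valid rows remain.
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype={"species": str, "sex": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"sample table missing required column(s): {missing}")

    samples: list[FishSample] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        if species_id is not None and str(row["species"]) != species_id:
            continue
        try:
            age = float(row["age"])
            if not age.is_integer():
                raise ValueError(f"age {age} is not an integer annulus count")
            samples.append(
                FishSample(
                    species_id=str(row["species"]),
                    sex=_parse_sex(row["sex"]),
                    age=int(age),
                    body_length=float(row["length_mm"]),
                    body_weight=float(row["weight_g"]),
                    site_id=_opt_str(row.get("site")),
                    season=_opt_str(row.get("season")),
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append({"row": int(idx), "reason": str(exc)})

    if not samples:
        raise InsufficientDataError(
            f"no valid rows in {path}" + (f" for species {species_id!r}" if species_id else "")
        )
    sid = species_id if species_id is not None else samples[0].species_id
    out = SampleSet(samples=[s for s in samples if s.species_id == sid], species_id=sid)
    out.rejected = rejected
    return out


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def write_samples(sample_set: SampleSet, path, *, delimiter: str = ",") -> None:
    """Write a sample table in the dialect :func:`read_samples` reads.

    Floats are written with shortest round-trip repr so a write/read
    cycle preserves every measurement bit-exactly.
    """
    sample_set.to_frame().to_csv(
        path, sep=delimiter, index=False, float_format=lambda v: repr(float(v))
    )


def split_species(path, *, delimiter: str = ",") -> dict[str, SampleSet]:
    """Read a mixed-species table and return one SampleSet per species."""
    df = pd.read_csv(path, sep=delimiter, dtype={"species": str})
    out = {}
    for sid in df["species"].unique():
        out[str(sid)] = read_samples(path, delimiter=delimiter, species_id=str(sid))
    return out


@dataclass(frozen=True)
class SampleSummary:
    """Catch summary mirroring a standard survey table."""

    species_id: str
    n: int
    n_female: int
    n_male: int
    n_unknown: int
    length_min: float
    length_max: float
    length_mean: float
    weight_min: float
    weight_max: float
    weight_mean: float
    age_min: int
    age_max: int
    male_to_female: float
    female_to_male: float


def summarize(sample_set: SampleSet) -> SampleSummary:
    """Counts, length/weight ranges and means, age range, sex ratios.

    Both sex-ratio orientations are reported because survey tables are
    frequently ambiguous about which sex the ratio leads with.
    """
    lengths = sample_set.lengths
    weights = sample_set.weights
    ages = sample_set.ages
    nf = sum(1 for s in sample_set if s.sex == "female")
    nm = sum(1 for s in sample_set if s.sex == "male")
    nu = sum(1 for s in sample_set if s.sex == "unknown")
    return SampleSummary(
        species_id=sample_set.species_id,
        n=len(sample_set),
        n_female=nf,
        n_male=nm,
        n_unknown=nu,
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=sum(lengths) / len(lengths),
        weight_min=min(weights),
        weight_max=max(weights),
        weight_mean=sum(weights) / len(weights),
        age_min=min(ages),
        age_max=max(ages),
        male_to_female=(nm / nf) if nf else float("inf"),
        female_to_male=(nf / nm) if nm else float("inf"),
    )


def summary_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Stack summaries into one table (one row per species)."""
    rows = [vars(s) for s in summaries]
    return pd.DataFrame(rows)
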