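"""Model parameter table: loading, validation, and sampling distributions.

The model is driven by a small table of cost and probability estimates, each
with a baseline value and a low-high sensitivity range (interpreted as a 95%
interval).  Probabilities are given per maternal-age band where the evidence
is age-dependent.  This module defines the typed container
(:class:`ParameterSet`), the bundled default table, file loaders for a
delimited and a YAML dialect, and method-of-moments distribution fitting used
by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "AgeBand",
    "AGE_BANDS",
    "ParameterEstimate",
    "ParameterSet",
    "ParameterDraw",
    "DistributionSpec",
    "ParameterValidationError",
    "PARAM_IDS",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "fit_distribution",
]


class AgeBand(str, enum.Enum):
    """Maternal-age stratum; ordering follows the parameter table."""

    UNDER_35 = "<35"
    AGE_35_37 = "35-37"
    AGE_38_40 = "38-40"
    AGE_41_42 = "41-42"
    OVER_42 = ">42"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "AgeBand | str") -> "AgeBand":
        """Accept an :class:`AgeBand` or a label (en-dash and spaces tolerated)."""
        if isinstance(value, cls):
            return value
        label = str(value).replace("–", "-").replace(" ", "")
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown age band {value!r}; expected one of "
                f"{[b.value for b in cls]}"
            ) from None


AGE_BANDS: tuple[AgeBand, ...] = tuple(AgeBand)

# Canonical parameter ids, in table order.  Banded ids carry one estimate per
# age band; scalar ids carry exactly one.
BANDED_IDS = ("p_iui", "p_ivf", "l_iui", "l_ivf")
SCALAR_IDS = ("c_iui", "c_ivf", "p_low_cs", "p_tiui")
COUNT_IDS = ("n_iui", "n_ivf")
PARAM_IDS = SCALAR_IDS + BANDED_IDS + COUNT_IDS

_KINDS = {"probability", "cost", "count"}
_EXPECTED_KIND = {
    "c_iui": "cost",
    "c_ivf": "cost",
    "p_low_cs": "probability",
    "p_tiui": "probability",
    "p_iui": "probability",
    "p_ivf": "probability",
    "l_iui": "probability",
    "l_ivf": "probability",
    "n_iui": "count",
    "n_ivf": "count",
}


class ParameterValidationError(ValueError):
    """Raised when a parameter table violates its schema or invariants."""

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__("invalid parameter table:\n  - " + "\n  - ".join(self.problems))


@dataclasses.dataclass(frozen=True)
class ParameterEstimate:
    """One table row: baseline value with a [low, high] sensitivity range."""

    id: str
    kind: str
    baseline: float
    low: float
    high: float
    age_band: AgeBand | None = None

    @property
    def key(self) -> str:
        """Unique name, e.g. ``p_ivf/38-40`` for banded, ``c_iui`` for scalar."""
        if self.age_band is None:
            return self.id
        return f"{self.id}/{self.age_band.value}"

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.kind not in _KINDS:
            out.append(f"{self.key}: unknown kind {self.kind!r}")
            return out
        if not (self.low <= self.baseline <= self.high):
            out.append(
                f"{self.key}: baseline {self.baseline} outside range "
                f"[{self.low}, {self.high}]"
            )
        if self.kind == "probability":
            for name, v in (("low", self.low), ("baseline", self.baseline), ("high", self.high)):
                if not 0.0 <= v <= 1.0:
                    out.append(f"{self.key}: {name} value {v} outside [0, 1]")
        elif self.kind == "cost":
            for name, v in (("low", self.low), ("baseline", self.baseline), ("high", self.high)):
                if v < 0:
                    out.append(f"{self.key}: {name} value {v} is negative")
        elif self.kind == "count":
            if self.baseline < 0 or self.baseline != int(self.baseline):
                out.append(f"{self.key}: count must be a non-negative integer")
        return out

    def validate(self) -> None:
        probs = self.problems()
        if probs:
            raise ParameterValidationError(probs)


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """Fitted sampling distribution for one uncertain parameter.

    ``family`` is one of ``beta`` (shapes ``alpha``/``beta_``), ``normal``
    (``mu``/``sigma``, truncated at zero when sampling), or ``point``
    (``value``).  :meth:`mean` reports the distribution's fitted location
    parameter (the untruncated mean for the normal family).
    """

    family: str
    alpha: float = math.nan
    beta_: float = math.nan
    mu: float = math.nan
    sigma: float = math.nan
    value: float = math.nan

    def mean(self) -> float:
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta_)
        if self.family == "normal":
            return self.mu
        return self.value

    def sd(self) -> float:
        if self.family == "beta":
            s = self.alpha + self.beta_
            return math.sqrt(self.alpha * self.beta_ / (s * s * (s + 1.0)))
        if self.family == "normal":
            return self.sigma
        return 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the fitted distribution (deterministic given ``rng``)."""
        if self.family == "beta":
            return rng.beta(self.alpha, self.beta_, size=size)
        if self.family == "normal":
            a = (0.0 - self.mu) / self.sigma
            return stats.truncnorm.rvs(
                a, np.inf, loc=self.mu, scale=self.sigma, size=size, random_state=rng
            )
        if size is None:
            return self.value
        return np.full(size, self.value)


# span / 3.92: the [low, high] range is read as a 95% interval.
_Z95_SPAN = 2.0 * 1.96


def fit_distribution(est: ParameterEstimate) -> DistributionSpec:
    """Fit a sampling distribution to an estimate.

    Probabilities get a beta distribution matched to mean = baseline and
    sd = (high - low) / 3.92 by the method of moments; costs get a normal
    with the same moments, truncated at zero when sampled.  A zero-width
    range (and any ``count``) collapses to a point mass.
    """
    est.validate()
    if est.low == est.high or est.kind == "count":
        return DistributionSpec(family="point", value=est.baseline)
    sd = (est.high - est.low) / _Z95_SPAN
    if est.kind == "cost":
        return DistributionSpec(family="normal", mu=est.baseline, sigma=sd)
    m = est.baseline
    var = sd * sd
    if var >= m * (1.0 - m):
        raise ValueError(
            f"{est.key}: method-of-moments beta infeasible "
            f"(variance {var:.6g} >= mean*(1-mean) {m * (1.0 - m):.6g}); "
            "reduce the sensitivity range"
        )
    nu = m * (1.0 - m) / var - 1.0
    return DistributionSpec(family="beta", alpha=m * nu, beta_=(1.0 - m) * nu)


@dataclasses.dataclass(frozen=True)
class ParameterDraw:
    """One concrete realization of every model quantity.

    Produced from a :class:`ParameterSet` either at baseline or by sampling;
    consumed by the tree evaluator and the cohort simulator.
    """

    c_iui: float
    c_ivf: float
    p_low_cs: float
    p_tiui: float
    p_iui: Mapping[AgeBand, float]
    p_ivf: Mapping[AgeBand, float]
    l_iui: Mapping[AgeBand, float]
    l_ivf: Mapping[AgeBand, float]
    n_iui: int = 3
    n_ivf: int = 3

    def validate(self) -> None:
        problems: list[str] = []
        for name in ("c_iui", "c_ivf"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: negative cost")
        scalars = {"p_low_cs": self.p_low_cs, "p_tiui": self.p_tiui}
        for name, v in scalars.items():
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: {v} outside [0, 1]")
        for name in ("p_iui", "p_ivf", "l_iui", "l_ivf"):
            mapping = getattr(self, name)
            for band in AGE_BANDS:
                if band not in mapping:
                    problems.append(f"{name}/{band.value}: missing")
                elif not 0.0 <= mapping[band] <= 1.0:
                    problems.append(f"{name}/{band.value}: {mapping[band]} outside [0, 1]")
        for name in ("n_iui", "n_ivf"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                problems.append(f"{name}: must be a non-negative integer")
        if problems:
            raise ParameterValidationError(problems)


class ParameterSet:
    """Validated collection of all model estimates plus the cycle caps."""

    def __init__(self, estimates: Mapping[str, ParameterEstimate]):
        self._estimates = dict(estimates)
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        problems: list[str] = []
        expected = self._expected_keys()
        for key in expected:
            if key not in self._estimates:
                problems.append(f"{key}: missing")
        for key, est in self._estimates.items():
            if key not in expected:
                problems.append(f"{key}: unknown parameter")
                continue
            if est.key != key:
                problems.append(f"{key}: estimate keyed inconsistently as {est.key}")
            if _EXPECTED_KIND[est.id] != est.kind:
                problems.append(
                    f"{key}: kind {est.kind!r} but {est.id} must be {_EXPECTED_KIND[est.id]!r}"
                )
            problems.extend(est.problems())
        if problems:
            raise ParameterValidationError(sorted(problems))

    @staticmethod
    def _expected_keys() -> list[str]:
        keys = list(SCALAR_IDS)
        for pid in BANDED_IDS:
            keys += [f"{pid}/{b.value}" for b in AGE_BANDS]
        keys += list(COUNT_IDS)
        return keys

    # -- access --------------------------------------------------------------

    def estimate(self, pid: str, band: AgeBand | str | None = None) -> ParameterEstimate:
        key = pid if band is None else f"{pid}/{AgeBand.coerce(band).value}"
        return self._estimates[key]

    def __getitem__(self, key: str) -> ParameterEstimate:
        return self._estimates[key]

    @property
    def n_iui(self) -> int:
        return int(self._estimates["n_iui"].baseline)

    @property
    def n_ivf(self) -> int:
        return int(self._estimates["n_ivf"].baseline)

    def uncertain_keys(self) -> list[str]:
        """All sampled parameter keys, in canonical table order."""
        keys = ["c_iui", "c_ivf", "p_low_cs"]
        keys += [f"p_iui/{b.value}" for b in AGE_BANDS]
        keys.append("p_tiui")
        for pid in ("p_ivf", "l_iui", "l_ivf"):
            keys += [f"{pid}/{b.value}" for b in AGE_BANDS]
        return keys

    def estimates(self) -> dict[str, ParameterEstimate]:
        return dict(self._estimates)

    # -- realizations ---------------------------------------------------------

    def baseline_draw(self) -> ParameterDraw:
        return self.draw_with({})

    def draw_with(self, overrides: Mapping[str, float]) -> ParameterDraw:
        """Baseline draw with selected keys replaced by concrete values."""
        unknown = set(overrides) - set(self._estimates)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")

        def val(key: str) -> float:
            if key in overrides:
                return float(overrides[key])
            return self._estimates[key].baseline

        def banded(pid: str) -> dict[AgeBand, float]:
            return {b: val(f"{pid}/{b.value}") for b in AGE_BANDS}

        draw = ParameterDraw(
            c_iui=val("c_iui"),
            c_ivf=val("c_ivf"),
            p_low_cs=val("p_low_cs"),
            p_tiui=val("p_tiui"),
            p_iui=banded("p_iui"),
            p_ivf=banded("p_ivf"),
            l_iui=banded("l_iui"),
            l_ivf=banded("l_ivf"),
            n_iui=self.n_iui,
            n_ivf=self.n_ivf,
        )
        draw.validate()
        return draw

    def fitted_distributions(self) -> dict[str, DistributionSpec]:
        return {k: fit_distribution(self._estimates[k]) for k in self.uncertain_keys()}

    def collapse_ranges(self) -> "ParameterSet":
        """Copy with every range collapsed to the baseline (degenerate PSA)."""
        collapsed = {
            key: dataclasses.replace(est, low=est.baseline, high=est.baseline)
            for key, est in self._estimates.items()
        }
        return ParameterSet(collapsed)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._estimates == other._estimates


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "age_band", "kind", "baseline", "low", "high"]


def _rows_to_set(rows: list[dict], origin: str) -> ParameterSet:
    problems: list[str] = []
    estimates: dict[str, ParameterEstimate] = {}
    for i, row in enumerate(rows, start=1):
        pid = str(row.get("id", "")).strip()
        if pid not in PARAM_IDS:
            problems.append(f"{origin} row {i}: unknown parameter id {pid!r}")
            continue
        band_raw = row.get("age_band") or None
        try:
            band = AgeBand.coerce(band_raw) if band_raw else None
        except ValueError as exc:
            problems.append(f"{origin} row {i}: {exc}")
            continue
        if pid in BANDED_IDS and band is None:
            problems.append(f"{origin} row {i}: {pid} requires an age band")
            continue
        if pid not in BANDED_IDS and band is not None:
            problems.append(f"{origin} row {i}: {pid} does not take an age band")
            continue
        try:
            est = ParameterEstimate(
                id=pid,
                kind=str(row["kind"]).strip(),
                baseline=float(row["baseline"]),
                low=float(row["low"]),
                high=float(row["high"]),
                age_band=band,
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"{origin} row {i}: malformed row ({exc})")
            continue
        if est.key in estimates:
            problems.append(f"{origin} row {i}: duplicate parameter {est.key}")
            continue
        estimates[est.key] = est
    if problems:
        raise ParameterValidationError(problems)
    return ParameterSet(estimates)


def _load_delimited(path: Path) -> ParameterSet:
    delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ParameterValidationError([f"{path}: empty file"])
        unknown = [c for c in reader.fieldnames if c not in _CSV_COLUMNS]
        missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
        problems = []
        problems += [f"{path}: unknown column {c!r}" for c in unknown]
        problems += [f"{path}: missing column {c!r}" for c in missing]
        if problems:
            raise ParameterValidationError(problems)
        rows = list(reader)
    return _rows_to_set(rows, str(path))


def _load_yaml(path: Path) -> ParameterSet:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterValidationError([f"{path}: top level must be a mapping"])
    problems: list[str] = []
    rows: list[dict] = []
    known_top = {"parameters", "n_iui", "n_ivf"}
    for key in doc:
        if key not in known_top:
            problems.append(f"{path}: unknown top-level key {key!r}")
    for cid in COUNT_IDS:
        if cid in doc:
            rows.append(
                {"id": cid, "age_band": None, "kind": "count",
                 "baseline": doc[cid], "low": doc[cid], "high": doc[cid]}
            )
    params = doc.get("parameters", {})
    if not isinstance(params, dict):
        problems.append(f"{path}: 'parameters' must be a mapping")
        params = {}
    for pid, entry in params.items():
        if not isinstance(entry, dict):
            problems.append(f"{path}: parameter {pid!r} must be a mapping")
            continue
        kind = entry.get("kind")
        if "by_age" in entry:
            for band, cell in entry["by_age"].items():
                rows.append({"id": pid, "age_band": band, "kind": kind, **_cell(cell)})
        else:
            rows.append({"id": pid, "age_band": None, "kind": kind, **_cell(entry)})
    if problems:
        raise ParameterValidationError(problems)
    return _rows_to_set(rows, str(path))


def _cell(entry: Mapping) -> dict:
    return {
        "baseline": entry.get("baseline"),
        "low": entry.get("low"),
        "high": entry.get("high"),
    }


def load_parameters(source: str | Path) -> ParameterSet:
    """Load and validate a parameter table from CSV/TSV or YAML."""
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _load_yaml(path)
    return _load_delimited(path)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter table to CSV (round-trips with :func:`load_parameters`)."""
    path = Path(path)
    order = {k: i for i, k in enumerate(ParameterSet._expected_keys())}
    ests = sorted(params.estimates().values(), key=lambda e: order[e.key])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for est in ests:
            writer.writerow(
                [
                    est.id,
                    est.age_band.value if est.age_band else "",
                    est.kind,
                    repr(est.baseline),
                    repr(est.low),
                    repr(est.high),
                ]
            )


def default_parameters_path() -> Path:
    """Path of the bundled default parameter table."""
    return Path(str(resources.files("artdecision").joinpath("data/default_parameters.csv")))


def default_parameters() -> ParameterSet:
    """The bundled default parameter table."""
    return load_parameters(default_parameters_path())
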