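"""Cohort data model for two-stage pregnancy-attempt follow-up.

One row per subject: baseline covariates ``w``; the observed first-stage
follow-up ``(U, delta)`` where ``U`` is the number of menstrual cycles under
observation and ``delta`` indicates a clinically-recognized pregnancy; the
second-stage gestation outcome (clinical loss / preterm / full-term); and
two non-missingness indicators ``R1`` (first-stage status known at ``tau``)
and ``R2`` (second-stage outcome known).

Conventions
-----------
* Cycles are 1-based integers; the conception window ``tau`` is a cohort
  property (default 6).
* Gestation outcomes keep the state-space coding 2 = loss, 3 = preterm,
  4 = full-term; "undefined" is stored as NaN.
* Subjects observed through ``tau`` without conception have ``R2 = 1``
  vacuously (their gestation outcome is undefined but not missing).
* A latent block (``latent_t1``, ``latent_c``, ``latent_y2``), emitted only
  by the simulator, records the true conception cycle, dropout cycle and
  gestation outcome; observed-data code never reads these columns.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

#: Canonical class order used everywhere, including HUM indexing.
CLASS_ORDER = ("no_pregnancy", "loss", "preterm", "fullterm")

#: Gestation-outcome state codes (full-term is the multinomial reference).
OUTCOME_CODES = {"loss": 2, "preterm": 3, "fullterm": 4}
OUTCOME_LABELS = {2: "loss", 3: "preterm", 4: "fullterm"}

REQUIRED_COLUMNS = ("id", "U", "conceived", "r1", "y2", "r2")
LATENT_COLUMNS = ("latent_t1", "latent_c", "latent_y2")


class ObservationPattern(enum.Enum):
    """The four observed-data categories of a pregnancy attempt."""

    CENSORED_PRECONCEPTION = "censored_preconception"
    NO_PREGNANCY = "no_pregnancy"
    PREGNANCY_UNKNOWN_RESULT = "pregnancy_unknown_result"
    PREGNANCY_KNOWN_RESULT = "pregnancy_known_result"


@dataclass(frozen=True)
class CovariateSchema:
    """Names and roles of the baseline covariates.

    Roles: ``x`` predicts conception, ``z`` predicts the gestation outcome,
    ``x_prime``/``z_prime`` predict first-/second-stage missingness, and
    ``aux`` are auxiliaries for imputation (default ``x`` union ``x_prime``).
    """

    x: tuple[str, ...]
    z: tuple[str, ...]
    x_prime: tuple[str, ...] = ()
    z_prime: tuple[str, ...] = ()
    aux: tuple[str, ...] | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for role in ("x", "z", "x_prime", "z_prime", "extra"):
            object.__setattr__(self, role, tuple(getattr(self, role)))
        if self.aux is not None:
            object.__setattr__(self, "aux", tuple(self.aux))

    @property
    def auxiliaries(self) -> tuple[str, ...]:
        if self.aux is not None:
            return self.aux
        seen: list[str] = []
        for name in self.x + self.x_prime:
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.x + self.z + self.x_prime + self.z_prime + self.auxiliaries + self.extra:
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    @classmethod
    def from_config(cls, path: str | Path) -> "CovariateSchema":
        """Load roles from a JSON or YAML mapping of role -> column list."""
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(
            x=raw.get("x", ()),
            z=raw.get("z", ()),
            x_prime=raw.get("x_prime", ()),
            z_prime=raw.get("z_prime", ()),
            aux=raw.get("aux"),
            extra=raw.get("extra", ()),
        )


@dataclass
class SubjectRecord:
    """Observed data for one pregnancy attempt."""

    id: object
    covariates: dict[str, float]
    followup_cycles: int
    conceived: int
    r1: int
    r2: int
    gestation_outcome: int | None = None  # 2, 3, 4, or None (undefined)
    latent: dict[str, float] | None = None


def _row_problems(row: pd.Series, tau: int) -> list[str]:
    problems = []
    u, d, r1, r2 = row["U"], row["conceived"], row["r1"], row["r2"]
    y2 = row["y2"]
    if not (1 <= u <= tau):
        problems.append(f"U={u} outside 1..{tau}")
    if d not in (0, 1) or r1 not in (0, 1) or r2 not in (0, 1):
        problems.append("conceived/r1/r2 must be 0/1")
        return problems
    if r2 == 1 and r1 == 0:
        problems.append("R2=1 with R1=0 violates sequential observation")
    if r1 == 0 and d == 1:
        problems.append("conception observed implies R1=1")
    if r1 == 1 and d == 0 and u != tau:
        problems.append(f"R1=1 without conception requires U=tau (got U={u})")
    if r1 == 1 and d == 0 and r2 == 0:
        problems.append("no-pregnancy subjects have R2=1 vacuously")
    if not pd.isna(y2):
        if y2 not in OUTCOME_LABELS:
            problems.append(f"y2={y2} not in {{2,3,4}}")
        if not (d == 1 and r1 == 1 and r2 == 1):
            problems.append("defined y2 requires conceived=1, R1=1, R2=1")
    elif d == 1 and r2 == 1:
        problems.append("known-result pregnancy must carry a y2 value")
    return problems


class Cohort:
    """An ordered collection of subjects with a covariate schema and ``tau``.

    Backed by a :class:`pandas.DataFrame` with the required columns
    ``id, U, conceived, r1, y2, r2`` plus one column per covariate and,
    optionally, the latent block.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        tau: int,
        schema: CovariateSchema,
        validate: bool = True,
    ) -> None:
        if tau < 1:
            raise ValueError("tau must be >= 1")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        missing_cov = [c for c in schema.names() if c not in df.columns]
        if missing_cov:
            raise ValueError(f"missing covariate columns: {missing_cov}")
        if len(df) == 0:
            raise ValueError("no subjects")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes[:5]}")
        self.df = df.reset_index(drop=True)
        self.tau = int(tau)
        self.schema = schema
        if validate:
            problems = self.validate()
            if problems:
                head = "; ".join(f"row {i}: {msg}" for i, msg in problems[:5])
                raise ValueError(f"{len(problems)} invalid rows ({head})")

    def validate(self) -> list[tuple[int, str]]:
        """Return (row index, message) for every invariant violation."""
        out: list[tuple[int, str]] = []
        for i, row in self.df.iterrows():
            for msg in _row_problems(row, self.tau):
                out.append((int(i), msg))
        return out

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return self.schema.names()

    def covariates(self) -> pd.DataFrame:
        return self.df[list(self.covariate_names)]

    def subjects(self) -> Iterator[SubjectRecord]:
        has_latent = all(c in self.df.columns for c in LATENT_COLUMNS)
        for _, row in self.df.iterrows():
            y2 = None if pd.isna(row["y2"]) else int(row["y2"])
            latent = (
                {c: row[c] for c in LATENT_COLUMNS} if has_latent else None
            )
            yield SubjectRecord(
                id=row["id"],
                covariates={c: row[c] for c in self.covariate_names},
                followup_cycles=int(row["U"]),
                conceived=int(row["conceived"]),
                r1=int(row["r1"]),
                r2=int(row["r2"]),
                gestation_outcome=y2,
                latent=latent,
            )

    def observation_patterns(self) -> pd.Series:
        """Vectorized pattern classification; partitions the cohort."""
        r1 = self.df["r1"].to_numpy()
        r2 = self.df["r2"].to_numpy()
        d = self.df["conceived"].to_numpy()
        out = np.empty(self.n, dtype=object)
        out[(r1 == 0) & (r2 == 0)] = ObservationPattern.CENSORED_PRECONCEPTION
        out[(r1 == 1) & (r2 == 1) & (d == 0)] = ObservationPattern.NO_PREGNANCY
        out[(r1 == 1) & (r2 == 0) & (d == 1)] = ObservationPattern.PREGNANCY_UNKNOWN_RESULT
        out[(r1 == 1) & (r2 == 1) & (d == 1)] = ObservationPattern.PREGNANCY_KNOWN_RESULT
        return pd.Series(out, index=self.df.index, name="pattern")

    def outcome_class(self) -> pd.Series:
        """Observed four-class outcome label; NaN where not verified."""
        labels = pd.Series(np.nan, index=self.df.index, dtype=object)
        verified = (self.df["r1"] == 1) & (self.df["r2"] == 1)
        nopreg = verified & (self.df["conceived"] == 0)
        labels[nopreg] = "no_pregnancy"
        known = verified & (self.df["conceived"] == 1)
        labels[known] = self.df.loc[known, "y2"].map(OUTCOME_LABELS)
        return labels

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Bootstrap resample of subjects (with replacement, fresh ids)."""
        idx = rng.integers(0, self.n, size=self.n)
        df = self.df.iloc[idx].reset_index(drop=True)
        df["id"] = np.arange(self.n)
        return Cohort(df, self.tau, self.schema, validate=False)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.tau, self.schema, validate=False)


def observation_pattern(record: SubjectRecord) -> ObservationPattern:
    """Classify a subject into one of the four observed-data categories."""
    key = (record.r1, record.r2)
    if key == (0, 1):
        raise ValueError("R1=0 with R2=1 violates sequential observation")
    if key == (0, 0):
        return ObservationPattern.CENSORED_PRECONCEPTION
    if record.conceived == 0:
        if record.r2 == 0:
            raise ValueError("no-pregnancy subjects have R2=1 vacuously")
        return ObservationPattern.NO_PREGNANCY
    if record.r2 == 0:
        return ObservationPattern.PREGNANCY_UNKNOWN_RESULT
    return ObservationPattern.PREGNANCY_KNOWN_RESULT


def read_cohort(
    path: str | Path,
    schema: CovariateSchema,
    tau: int = 6,
    on_invalid: str = "drop",
) -> Cohort:
    """Read a comma-delimited cohort file (header row, UTF-8).

    Rows violating the subject-record invariants are rejected with
    row-indexed diagnostics (``on_invalid="drop"``, recorded on
    ``cohort.diagnostics``) or raise (``on_invalid="raise"``).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("no subjects")
    diagnostics: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        problems = _row_problems(row, tau)
        if problems:
            keep[i] = False
            for msg in problems:
                diagnostics.append((int(i), msg))
    if diagnostics and on_invalid == "raise":
        head = "; ".join(f"row {i}: {msg}" for i, msg in diagnostics[:5])
        raise ValueError(f"{len(diagnostics)} invalid rows ({head})")
    df = df.loc[keep]
    if len(df) == 0:
        raise ValueError("no subjects (all rows rejected)")
    cohort = Cohort(df, tau, schema, validate=False)
    cohort.diagnostics = diagnostics  # type: ignore[attr-defined]
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort data section as canonical CSV (UTF-8, header row)."""
    cohort.df.to_csv(path, index=False)


def expand_person_period(cohort: Cohort) -> pd.DataFrame:
    """Cycle-level expansion of first-stage follow-up.

    Subject ``i`` contributes ``U_i`` rows for cycles ``1..U_i`` with the
    binary outcome ``event = I(delta_i = 1 and t = U_i)``; baseline
    covariates are copied unchanged to every duplicate.  The total row
    count is ``N = sum_i U_i`` and the logistic log-likelihood on these
    rows equals the discrete-time survival log-likelihood.
    """
    u = cohort.df["U"].to_numpy(dtype=int)
    d = cohort.df["conceived"].to_numpy(dtype=int)
    reps = np.repeat(np.arange(cohort.n), u)
    t = np.concatenate([np.arange(1, ui + 1) for ui in u])
    event = (t == np.repeat(u, u)) & (np.repeat(d, u) == 1)
    out = cohort.df.iloc[reps][["id"] + list(cohort.covariate_names)].reset_index(drop=True)
    out.insert(1, "t", t)
    out.insert(2, "event", event.astype(int))
    return out
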