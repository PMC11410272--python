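"""Cohort, score, phenotype and carrier tables: domain types, TSV I/O,
alignment and validation.

All tables are tab-separated UTF-8 with a header row; ``NA`` or an empty
field means missing.  Column names are configurable through a
``column_map`` argument (``{file_column: canonical_name}``) so that files
produced by other pipelines can be read without rewriting them.

The canonical in-memory container is a :class:`pandas.DataFrame` wrapped in
a thin dataclass that records validation diagnostics.  Alignment of cohort,
scores and phenotype is an inner join on ``individual_id`` (complete-case
analysis); the number of rows dropped from each side is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EstimationError, ValidationError

SEXES = ("female", "male")
#: Ancestry labels reported on by default; anything else passes through as
#: "other" and is excluded from per-ancestry summaries unless asked for.
DEFAULT_ANCESTRIES = ("EUR", "SAS", "AFR", "EAS")

_COHORT_COLS = ("individual_id", "sex", "age_at_assessment", "ancestry", "censor_age")
_PARENT_COLS = ("individual_id", "parent_sex", "parent_age", "parent_dead")


def _read_tsv(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}, na_values=["NA", ""])
    if column_map:
        df = df.rename(columns=dict(column_map))
        if "individual_id" in df.columns:
            df["individual_id"] = df["individual_id"].astype(str)
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the package dialect (TSV, ``NA`` for missing)."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class CohortTable:
    """Per-individual covariates and follow-up.

    ``data`` columns: ``individual_id`` (unique string), ``sex``
    (female/male, may be missing), ``age_at_assessment`` (years),
    ``ancestry`` (label), ``censor_age`` (age at last follow-up or death),
    optional ``death_age``.  ``parents`` holds one row per parent
    (``parent_sex``, ``parent_age`` = age at death or censoring,
    ``parent_dead`` flag).
    """

    data: pd.DataFrame
    parents: pd.DataFrame | None = None
    diagnostics: list[str] = field(default_factory=list)
    n_rejected: int = 0

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.data["individual_id"])

    def ancestry_groups(self, include_other: bool = False) -> list[str]:
        labels = [a for a in DEFAULT_ANCESTRIES if a in set(self.data["ancestry"])]
        if include_other:
            labels += sorted(set(self.data["ancestry"]) - set(DEFAULT_ANCESTRIES))
        return labels


@dataclass
class ScoreSet:
    """One or more named PRS columns keyed by ``individual_id``.

    ``metadata`` maps score name -> ``{"trait": ..., "source": ...}`` where
    source is ``enhanced``, ``standard`` or ``comparator``.
    """

    data: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    @property
    def score_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "individual_id"]

    def source_of(self, name: str) -> str:
        return self.metadata.get(name, {}).get("source", "unknown")


@dataclass
class BinaryPhenotype:
    """Case/control status with age at diagnosis.

    ``data`` columns: ``individual_id``, ``case_flag`` (0/1), ``event_age``
    (years, required iff case).  ``sex_restriction`` removes the other sex
    at alignment time; ``age_window`` limits curve display (e.g. type 1
    diabetes 0-20).
    """

    trait_code: str
    data: pd.DataFrame = None
    sex_restriction: str | None = None
    age_window: tuple[float, float] | None = None


@dataclass
class QuantPhenotype:
    """A quantitative trait value per individual (``value`` column)."""

    trait_code: str
    data: pd.DataFrame = None
    sex_restriction: str | None = None


@dataclass
class CarrierTable:
    """Rare pathogenic-variant carrier flags for one gene set."""

    data: pd.DataFrame = None
    gene_set: str = ""

    def validate(self) -> "CarrierTable":
        _require_columns(self.data, ("individual_id", "carrier_flag"), "carrier table")
        freq = self.data["carrier_flag"].mean()
        if not 0 < freq < 1:
            raise ValidationError(
                f"carrier frequency must be strictly between 0 and 1, got {freq:.4g}"
            )
        return self


@dataclass
class AnalysisConfig:
    """Knobs of the standardised evaluation.

    Defaults follow the published evaluation design: percentile bands
    top 3% / median 40-60% / bottom 3%; per-ancestry metrics need at least
    100 cases; cumulative-incidence curves need more than 40 cases;
    5000 paired bootstrap resamples.
    """

    band_definitions: list[tuple[float, float]] = field(
        default_factory=lambda: [(97.0, 100.0), (40.0, 60.0), (0.0, 3.0)]
    )
    min_cases_metric: int = 100
    min_cases_curve: int = 40
    n_bootstrap: int = 5000
    random_seed: int = 0
    incidence_mode: str = "lifetime"  # or "incident"
    covariates: tuple[str, ...] = ("age_at_assessment", "sex")
    ancestries: tuple[str, ...] = DEFAULT_ANCESTRIES

    def __post_init__(self) -> None:
        for lo, hi in self.band_definitions:
            if not (0 <= lo < hi <= 100):
                raise ConfigError(f"band ({lo}, {hi}) not within [0, 100] or empty")
        for (lo1, hi1) in self.band_definitions:
            for (lo2, hi2) in self.band_definitions:
                if (lo1, hi1) < (lo2, hi2) and lo2 < hi1 and lo1 < hi2:
                    raise ConfigError(
                        f"bands ({lo1},{hi1}) and ({lo2},{hi2}) overlap"
                    )
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.incidence_mode not in ("lifetime", "incident"):
            raise ConfigError(f"unknown incidence_mode {self.incidence_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_definitions" in raw:
            raw["band_definitions"] = [tuple(b) for b in raw["band_definitions"]]
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        if "ancestries" in raw:
            raw["ancestries"] = tuple(raw["ancestries"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    incident_mode: bool = False,
    parents_path: str | Path | None = None,
) -> CohortTable:
    """Read and validate a cohort table.

    Rows violating row-level invariants (negative ages, censor age before
    assessment in incident mode, death after censoring, case semantics) are
    rejected and counted; duplicate ids are a hard error naming the ids.
    """
    df = _read_tsv(path, column_map)
    _require_columns(df, _COHORT_COLS, "cohort table")

    dup = df["individual_id"][df["individual_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate individual_id values: {sorted(dup)}")

    diagnostics: list[str] = []
    ok = pd.Series(True, index=df.index)

    bad_sex = df["sex"].notna() & ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"unrecognised sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}"
        )

    bad_age = ~(df["age_at_assessment"] > 0)
    if bad_age.any():
        diagnostics.append(f"{int(bad_age.sum())} row(s) with non-positive age_at_assessment")
        ok &= ~bad_age
    if incident_mode:
        bad_censor = df["censor_age"] < df["age_at_assessment"]
        if bad_censor.any():
            diagnostics.append(
                f"{int(bad_censor.sum())} row(s) with censor_age < age_at_assessment "
                "(rejected in incident mode)"
            )
            ok &= ~bad_censor
    if "death_age" in df.columns:
        bad_death = df["death_age"].notna() & (df["death_age"] > df["censor_age"])
        if bad_death.any():
            diagnostics.append(f"{int(bad_death.sum())} row(s) with death_age > censor_age")
            ok &= ~bad_death

    parents = None
    if parents_path is not None:
        parents = _read_tsv(parents_path, column_map)
        _require_columns(parents, _PARENT_COLS, "parent table")
        parents = parents[parents["individual_id"].isin(df.loc[ok, "individual_id"])]

    return CohortTable(
        data=df[ok].reset_index(drop=True),
        parents=parents,
        diagnostics=diagnostics,
        n_rejected=int((~ok).sum()),
    )


def read_scores(
    path: str | Path,
    metadata: Mapping[str, dict] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ScoreSet:
    df = _read_tsv(path, column_map)
    _require_columns(df, ("individual_id",), "score table")
    if df.shape[1] < 2:
        raise ConfigError("score table has no score columns")
    dup = df["individual_id"][df["individual_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate individual_id values in scores: {sorted(dup)}")
    return ScoreSet(data=df, metadata=dict(metadata or {}))


def read_binary_phenotype(
    path: str | Path,
    trait_code: str,
    sex_restriction: str | None = None,
    age_window: tuple[float, float] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> BinaryPhenotype:
    """Read a binary phenotype; event age must be present iff case.

    Cases with a missing age at diagnosis are rejected rather than imputed
    (reported in the returned object's frame length vs the file).
    """
    df = _read_tsv(path, column_map)
    _require_columns(df, ("individual_id", "case_flag", "event_age"), f"phenotype {trait_code}")
    bad = (df["case_flag"] == 1) & df["event_age"].isna()
    bad |= (df["case_flag"] == 0) & df["event_age"].notna()
    df = df[~bad].reset_index(drop=True)
    return BinaryPhenotype(
        trait_code=trait_code, data=df, sex_restriction=sex_restriction, age_window=age_window
    )


def read_quant_phenotype(
    path: str | Path,
    trait_code: str,
    sex_restriction: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> QuantPhenotype:
    df = _read_tsv(path, column_map)
    _require_columns(df, ("individual_id", "value"), f"phenotype {trait_code}")
    df = df[np.isfinite(df["value"])].reset_index(drop=True)
    return QuantPhenotype(trait_code=trait_code, data=df, sex_restriction=sex_restriction)


def read_carriers(
    path: str | Path, gene_set: str = "", column_map: Mapping[str, str] | None = None
) -> CarrierTable:
    df = _read_tsv(path, column_map)
    return CarrierTable(data=df, gene_set=gene_set).validate()


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AnalysisFrame:
    """Inner join of cohort, scores and one phenotype.

    ``data`` carries cohort columns, all score columns, and either
    (``case_flag``, ``event_age``) or ``value``.  ``dropped`` records how
    many ids each input lost in the join and to the sex restriction.
    """

    data: pd.DataFrame
    trait_code: str
    kind: str  # "binary" | "quant"
    dropped: dict[str, int] = field(default_factory=dict)
    sex_restriction: str | None = None
    age_window: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        if self.kind != "binary":
            raise EstimationError("n_cases only defined for binary phenotypes")
        return int((self.data["case_flag"] == 1).sum())

    def subset(self, mask: pd.Series | np.ndarray) -> "AnalysisFrame":
        return AnalysisFrame(
            data=self.data[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            trait_code=self.trait_code,
            kind=self.kind,
            dropped=dict(self.dropped),
            sex_restriction=self.sex_restriction,
            age_window=self.age_window,
        )


def align(
    cohort: CohortTable,
    scores: ScoreSet,
    pheno: BinaryPhenotype | QuantPhenotype,
) -> AnalysisFrame:
    """Inner-join cohort, scores and phenotype on ``individual_id``.

    Applies the phenotype's sex restriction (rows of the other sex, and
    rows with missing sex, are excluded).  Raises if the key intersection
    is empty.
    """
    kind = "binary" if isinstance(pheno, BinaryPhenotype) else "quant"
    c, s, p = cohort.data, scores.data, pheno.data
    merged = c.merge(s, on="individual_id", how="inner").merge(
        p, on="individual_id", how="inner"
    )
    if merged.empty:
        raise EstimationError(
            f"empty intersection of ids between cohort ({len(c)}), "
            f"scores ({len(s)}) and phenotype ({len(p)})"
        )
    kept = set(merged["individual_id"])
    dropped = {
        "cohort": int((~c["individual_id"].isin(kept)).sum()),
        "scores": int((~s["individual_id"].isin(kept)).sum()),
        "phenotype": int((~p["individual_id"].isin(kept)).sum()),
    }
    n_sex_dropped = 0
    if pheno.sex_restriction is not None:
        if pheno.sex_restriction not in SEXES:
            raise ConfigError(f"unknown sex restriction {pheno.sex_restriction!r}")
        keep = merged["sex"] == pheno.sex_restriction
        n_sex_dropped = int((~keep).sum())
        merged = merged[keep]
        if merged.empty:
            raise EstimationError(
                f"no individuals of sex {pheno.sex_restriction!r} after alignment"
            )
    dropped["sex_restriction"] = n_sex_dropped
    merged = merged.sort_values("individual_id", kind="stable").reset_index(drop=True)
    return AnalysisFrame(
        data=merged,
        trait_code=pheno.trait_code,
        kind=kind,
        dropped=dropped,
        sex_restriction=pheno.sex_restriction,
        age_window=getattr(pheno, "age_window", None),
    )


def distribution_summary(scores: ScoreSet, cohort: CohortTable) -> pd.DataFrame:
    """Raw-score mean and SD per (score, ancestry), SD with n-1 denominator.

    Groups with fewer than two observations get a flag and no SD; a
    zero-variance column gets a ``degenerate`` flag.
    """
    merged = cohort.data[["individual_id", "ancestry"]].merge(
        scores.data, on="individual_id", how="inner"
    )
    rows = []
    for name in scores.score_names:
        for anc, grp in merged.groupby("ancestry", sort=True):
            vals = grp[name].dropna().to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            if n < 2:
                rows.append((name, anc, mean, np.nan, n, "n<2"))
                continue
            sd = float(np.std(vals, ddof=1))
            flag = "degenerate" if sd == 0 else ""
            rows.append((name, anc, mean, sd, n, flag))
    return pd.DataFrame(
        rows, columns=["score_name", "ancestry", "mean", "sd", "n", "flag"]
    )
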