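"""Visual rating scale specifications and score tables.

Three classic WMH visual rating scales are shipped:

* **Manolio** — a single global impression score, 0 (no lesions) to 9.
* **Fazekas** — periventricular (PV) and deep white matter (DWM)
  subscales, each 0-3, plus their sum as a composite.
* **Scheltens** — regional subscales: three periventricular items
  (frontal caps, lateral bands, occipital caps; each 0-2, total 0-6),
  four deep-white-matter lobar items (each 0-6, total 0-24), five basal
  ganglia items (each 0-6, total 0-30) and four infratentorial items
  (each 0-6, total 0-24).

Scores live in long-format tables (subject, rater, subscale, score);
missing entries are explicit NaN, never silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Subscale",
    "ScaleSpec",
    "ScoreTable",
    "ScoreValidationError",
    "MANOLIO",
    "FAZEKAS",
    "SCHELTENS",
    "BUILTIN_SCALES",
    "validate_scores",
    "mean_scores",
]

log = logging.getLogger(__name__)


class ScoreValidationError(ValueError):
    """Raised when scores fall outside their subscale's admissible range."""

    def __init__(self, violations: list[tuple]):
        self.violations = violations
        lines = ", ".join(
            f"(subject={s}, rater={r}, subscale={sub}, score={v})"
            for s, r, sub, v in violations[:10]
        )
        more = "" if len(violations) <= 10 else f" … and {len(violations) - 10} more"
        super().__init__(f"{len(violations)} out-of-range score(s): {lines}{more}")


@dataclass(frozen=True)
class Subscale:
    id: str
    min_score: int
    max_score: int

    def admits(self, value: float) -> bool:
        return self.min_score <= value <= self.max_score


@dataclass(frozen=True)
class ScaleSpec:
    """A visual rating scale: named subscales with ranges and composites."""

    name: str
    subscales: tuple[Subscale, ...]
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def subscale(self, sid: str) -> Subscale:
        for s in self.subscales:
            if s.id == sid:
                return s
        raise KeyError(f"{self.name} has no subscale {sid!r}")

    @property
    def subscale_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.subscales)

    def composite_range(self, name: str) -> tuple[int, int]:
        ids = self.composites[name]
        lo = sum(self.subscale(i).min_score for i in ids)
        hi = sum(self.subscale(i).max_score for i in ids)
        return lo, hi


MANOLIO = ScaleSpec(
    name="Manolio",
    subscales=(Subscale("Manolio", 0, 9),),
)

FAZEKAS = ScaleSpec(
    name="Fazekas",
    subscales=(Subscale("PV", 0, 3), Subscale("DWM", 0, 3)),
    composites={"Tot": ("PV", "DWM")},
)

# Scheltens regional subscales. Periventricular items are scored 0-2; all
# other items 0-6. Block totals: PV 0-6, deep WM 0-24, basal ganglia 0-30,
# infratentorial 0-24.
SCHELTENS = ScaleSpec(
    name="Scheltens",
    subscales=(
        # periventricular: frontal caps, lateral bands, occipital caps
        Subscale("FC", 0, 2),
        Subscale("LB", 0, 2),
        Subscale("PC", 0, 2),
        # deep white matter, per lobe
        Subscale("DWMF", 0, 6),
        Subscale("DWMP", 0, 6),
        Subscale("DWMO", 0, 6),
        Subscale("DWMT", 0, 6),
        # basal ganglia, per structure
        Subscale("BGCN", 0, 6),
        Subscale("BGPU", 0, 6),
        Subscale("BGGP", 0, 6),
        Subscale("BGTH", 0, 6),
        Subscale("BGIC", 0, 6),
        # infratentorial, per structure
        Subscale("ITCE", 0, 6),
        Subscale("ITME", 0, 6),
        Subscale("ITPO", 0, 6),
        Subscale("ITMO", 0, 6),
    ),
    composites={
        "PVTot": ("FC", "LB", "PC"),
        "DWMTot": ("DWMF", "DWMP", "DWMO", "DWMT"),
        "BGTot": ("BGCN", "BGPU", "BGGP", "BGTH", "BGIC"),
        "ITTot": ("ITCE", "ITME", "ITPO", "ITMO"),
        "PartialTot": ("FC", "LB", "PC", "DWMF", "DWMP", "DWMO", "DWMT"),
        "Tot": (
            "FC", "LB", "PC", "DWMF", "DWMP", "DWMO", "DWMT",
            "BGCN", "BGPU", "BGGP", "BGTH", "BGIC",
            "ITCE", "ITME", "ITPO", "ITMO",
        ),
    },
)

BUILTIN_SCALES: dict[str, ScaleSpec] = {
    s.name.lower(): s for s in (MANOLIO, FAZEKAS, SCHELTENS)
}


@dataclass
class ScoreTable:
    """Long-format ordinal scores: one row per (subject, rater, subscale).

    ``data`` columns: ``subject``, ``rater``, ``subscale``, ``score``.
    Missing scores are NaN.
    """

    data: pd.DataFrame
    scale: ScaleSpec

    REQUIRED = ("subject", "rater", "subscale", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"score table missing columns {missing}")
        self.data = self.data.loc[:, list(self.REQUIRED)].copy()
        self.data["score"] = self.data["score"].astype(float)
        unknown = set(self.data["subscale"]) - set(self.scale.subscale_ids)
        if unknown:
            raise ValueError(
                f"subscales {sorted(unknown)} not in scale {self.scale.name}"
            )

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject"].unique().tolist())

    @property
    def raters(self) -> list:
        return sorted(self.data["rater"].unique().tolist())

    def wide(self, subscale: str) -> pd.DataFrame:
        """subjects x raters matrix of one subscale's scores."""
        sub = self.data[self.data["subscale"] == subscale]
        return sub.pivot_table(index="subject", columns="rater",
                               values="score", aggfunc="first")

    def with_composites(self) -> "ScoreTable":
        """Append composite rows (sums of subscales) per subject and rater."""
        frames = [self.data]
        spec = self.scale
        comp_subscales = list(spec.subscales)
        for name, ids in spec.composites.items():
            sub = self.data[self.data["subscale"].isin(ids)]
            agg = (
                sub.groupby(["subject", "rater"], sort=False)["score"]
                .agg(lambda s: s.sum() if s.notna().all() and len(s) == len(ids) else np.nan)
                .reset_index()
            )
            agg["subscale"] = name
            frames.append(agg[["subject", "rater", "subscale", "score"]])
            lo, hi = spec.composite_range(name)
            comp_subscales.append(Subscale(name, lo, hi))
        wide_spec = ScaleSpec(spec.name, tuple(comp_subscales), {})
        return ScoreTable(pd.concat(frames, ignore_index=True), wide_spec)

    @classmethod
    def from_csv(cls, path, scale: ScaleSpec) -> "ScoreTable":
        return cls(pd.read_csv(path), scale)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def validate_scores(table: ScoreTable, spec: ScaleSpec | None = None) -> ScoreTable:
    """Check every non-missing score against its subscale range.

    Returns the table unchanged when all scores are admissible; raises
    :class:`ScoreValidationError` listing every offending
    (subject, rater, subscale, score) otherwise. Idempotent.
    """
    spec = spec or table.scale
    violations = []
    for row in table.data.itertuples(index=False):
        if np.isnan(row.score):
            continue
        if not spec.subscale(row.subscale).admits(row.score):
            violations.append((row.subject, row.rater, row.subscale, row.score))
    if violations:
        raise ScoreValidationError(violations)
    return table


def mean_scores(table: ScoreTable, raters: list | None = None) -> pd.DataFrame:
    """Consensus scores: arithmetic mean over the selected raters.

    Subjects with any missing score among the selected raters are dropped
    from the result (a count is logged). Returns a subjects x subscales
    DataFrame; with k raters every entry is a multiple of 1/k.
    """
    if raters is not None and len(raters) == 0:
        raise ValueError("empty rater subset")
    raters = list(raters) if raters is not None else table.raters
    sub = table.data[table.data["rater"].isin(raters)]
    missing_raters = set(raters) - set(sub["rater"])
    if missing_raters:
        raise ValueError(f"raters not in table: {sorted(missing_raters)}")
    wide = sub.pivot_table(index="subject", columns="subscale", values="score",
                           aggfunc="mean", dropna=False)
    # a subject is complete if every selected rater scored every subscale
    counts = sub.dropna(subset=["score"]).groupby(["subject", "subscale"]).size()
    n_sub = wide.shape[1]
    complete = counts.groupby("subject").agg(
        lambda s: (s == len(raters)).all()
    )
    full = counts.groupby("subject").size() == n_sub
    keep = complete & full
    keep_ids = keep[keep].index
    dropped = len(wide.index) - len(keep_ids)
    if dropped:
        log.info("mean_scores: dropped %d subject(s) with missing scores", dropped)
    return wide.loc[keep_ids]
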