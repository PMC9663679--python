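"""Patient data model, cohort CSV I/O, and reconstruction of the study cohort.

The study cohort (115 emergency-department patients with suspected nonvariceal
upper-GI bleeding, 35 of whom had a high-risk endoscopic lesion, HREL) was never
deposited as patient-level data.  It is, however, fully identifiable from two
printed summaries:

* cumulative rule-out counts at every score cutoff, by HREL status, for both
  the Glasgow-Blatchford score (GBS) and the combined GBS + nasogastric-aspirate
  (NGA) score, and
* the bloody / non-bloody NGA split within each HREL stratum (24/11 bloody
  among HREL patients / non-HREL patients).

Because every non-bloody patient's combined score equals their GBS while every
bloody patient's combined score is 23, first differences of the two cumulative
tables identify the full joint distribution of (GBS, bloody NGA, HREL).
:func:`reconstruct_cohort` materialises it as patient records, deterministically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NGA_CATEGORIES = ("bloody", "coffee_ground", "bile_like", "clear")
NON_BLOODY = ("coffee_ground", "bile_like", "clear")

GBS_MIN, GBS_MAX = 0, 23

#: Columns of the cohort CSV dialect (UTF-8, comma separated, booleans as 0/1).
CSV_COLUMNS = (
    "id", "age", "sex", "hematemesis", "melena", "syncope", "sbp", "dbp",
    "pulse", "hemoglobin_g_dl", "bun_value", "bun_unit", "hepatic_disease",
    "cardiac_failure", "nga", "hrel", "gbs",
)

_RAW_GBS_FIELDS = (
    "sex", "melena", "syncope", "sbp", "pulse", "hemoglobin_g_dl",
    "bun_value", "hepatic_disease", "cardiac_failure",
)


class CohortError(ValueError):
    """Raised for invalid cohort files or inconsistent summary tables."""


@dataclass
class PatientRecord:
    """One emergency-department patient.

    Clinical fields are optional: a record is usable as long as it carries
    either a precomputed ``gbs`` or all raw variables needed to compute one.
    ``hemoglobin_g_dl`` is in g/dL; ``bun_value`` comes with a declared
    ``bun_unit`` ("mg_dl" or "mmol_l").
    """

    id: str
    nga: str
    hrel: bool
    gbs: int | None = None
    age: float | None = None
    sex: str | None = None
    hematemesis: bool | None = None
    melena: bool | None = None
    syncope: bool | None = None
    sbp: float | None = None
    dbp: float | None = None
    pulse: float | None = None
    hemoglobin_g_dl: float | None = None
    bun_value: float | None = None
    bun_unit: str | None = None
    hepatic_disease: bool | None = None
    cardiac_failure: bool | None = None

    def __post_init__(self) -> None:
        if self.nga not in NGA_CATEGORIES:
            raise CohortError(
                f"patient {self.id!r}: unknown NGA category {self.nga!r} "
                f"(expected one of {NGA_CATEGORIES})"
            )
        if self.gbs is not None:
            if self.gbs != int(self.gbs) or not GBS_MIN <= int(self.gbs) <= GBS_MAX:
                raise CohortError(
                    f"patient {self.id!r}: gbs={self.gbs!r} outside [{GBS_MIN}, {GBS_MAX}]"
                )
            self.gbs = int(self.gbs)
        elif not self.has_raw_variables:
            raise CohortError(
                f"patient {self.id!r}: neither gbs nor the full set of raw "
                "clinical variables is present"
            )
        if self.bun_value is not None and self.bun_unit not in ("mg_dl", "mmol_l"):
            raise CohortError(
                f"patient {self.id!r}: bun_value given without a valid bun_unit"
            )

    @property
    def has_raw_variables(self) -> bool:
        return all(getattr(self, f) is not None for f in _RAW_GBS_FIELDS)

    @property
    def bloody(self) -> bool:
        """Binary NGA: bloody vs non-bloody (coffee-ground / bile-like / clear)."""
        return self.nga == "bloody"


@dataclass(frozen=True)
class CumulativeCountTable:
    """Cumulative rule-out counts at each score cutoff, by HREL status.

    Row k holds the number of patients with score <= cutoffs[k] in each
    stratum; the first row is the count at score 0 (i.e. <=0).
    """

    cutoffs: tuple[int, ...]
    cum_with_hrel: tuple[int, ...]
    cum_without_hrel: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.cutoffs)
        if not (len(self.cum_with_hrel) == len(self.cum_without_hrel) == n) or n == 0:
            raise CohortError("cumulative table: ragged or empty columns")
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise CohortError("cumulative table: cutoffs must be strictly increasing")
        for name in ("cum_with_hrel", "cum_without_hrel"):
            col = getattr(self, name)
            if any(c < 0 for c in col):
                raise CohortError(f"cumulative table: negative count in {name}")
            if any(b < a for a, b in zip(col, col[1:])):
                raise CohortError(f"cumulative table: {name} is not non-decreasing")

    @property
    def totals(self) -> tuple[int, int]:
        return self.cum_with_hrel[-1], self.cum_without_hrel[-1]

    def per_score_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """First differences: counts of patients at each exact score value.

        Returns arrays indexed by score 0..max(cutoffs); scores absent from
        ``cutoffs`` get zero.
        """
        size = self.cutoffs[-1] + 1
        w = np.zeros(size, dtype=int)
        wo = np.zeros(size, dtype=int)
        prev_w = prev_wo = 0
        for k, cw, cwo in zip(self.cutoffs, self.cum_with_hrel, self.cum_without_hrel):
            w[k] = cw - prev_w
            wo[k] = cwo - prev_wo
            prev_w, prev_wo = cw, cwo
        return w, wo

    @classmethod
    def from_per_score_counts(
        cls, with_hrel: Sequence[int], without_hrel: Sequence[int],
        cutoffs: Sequence[int] | None = None,
    ) -> "CumulativeCountTable":
        w = np.asarray(with_hrel, dtype=int)
        wo = np.asarray(without_hrel, dtype=int)
        if cutoffs is None:
            cutoffs = range(len(w))
        cw = np.cumsum(w)
        cwo = np.cumsum(wo)
        return cls(
            tuple(int(k) for k in cutoffs),
            tuple(int(cw[k]) for k in cutoffs),
            tuple(int(cwo[k]) for k in cutoffs),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CumulativeCountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            tuple(int(v) for v in df["cutoff"]),
            tuple(int(v) for v in df["cum_with_hrel"]),
            tuple(int(v) for v in df["cum_without_hrel"]),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "cutoff": self.cutoffs,
            "cum_with_hrel": self.cum_with_hrel,
            "cum_without_hrel": self.cum_without_hrel,
        }).to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(resources.files("nvugib.data") / name)  # type: ignore[arg-type]


def study_tables() -> tuple[CumulativeCountTable, CumulativeCountTable]:
    """The study's printed cumulative tables (GBS block, algorithm block)."""
    return (
        CumulativeCountTable.from_tsv(_data_path("cumulative_gbs.tsv")),
        CumulativeCountTable.from_tsv(_data_path("cumulative_algorithm.tsv")),
    )


#: Bloody-NGA patients by HREL stratum: (with HREL, without HREL).
STUDY_BLOODY_COUNTS = (24, 11)

#: Non-bloody NGA category counts (coffee_ground, bile_like, clear) by HREL
#: stratum, as printed in the baseline-characteristics table.
STUDY_NON_BLOODY_CATEGORIES: dict[bool, tuple[int, int, int]] = {
    True: (8, 0, 3),
    False: (44, 6, 19),
}


def reconstruct_cohort(
    gbs_table: CumulativeCountTable,
    algo_table: CumulativeCountTable,
    bloody_counts: tuple[int, int] = STUDY_BLOODY_COUNTS,
    non_bloody_categories: Mapping[bool, tuple[int, int, int]] | None = None,
) -> list[PatientRecord]:
    """Rebuild patient-level (GBS, bloody NGA, HREL) records from summary tables.

    ``algo_table`` is the combined-score table restricted to cutoffs below 23;
    its columns count only non-bloody patients (whose combined score equals
    their GBS), so the bloody patients' GBS distribution is the per-score
    difference between the two tables, within each HREL stratum.

    Record ids are "P001".. in the stable order (HREL desc, bloody desc,
    GBS asc), which makes reconstruction deterministic and snapshot-friendly.

    ``non_bloody_categories`` optionally gives the (coffee_ground, bile_like,
    clear) counts per HREL stratum; the categories are assigned to non-bloody
    patients in that order along ascending GBS.  The category-by-GBS joint is
    not identifiable from the summary tables, so this only fixes the marginal
    category counts; omitted, every non-bloody patient is recorded as "clear".
    """
    n_bloody_w, n_bloody_wo = bloody_counts
    gw, gwo = gbs_table.per_score_counts()
    aw, awo = algo_table.per_score_counts()
    size = max(len(gw), len(aw))
    gw, gwo, aw, awo = (np.pad(a, (0, size - len(a))) for a in (gw, gwo, aw, awo))

    if (algo_table.totals[0] + n_bloody_w != gbs_table.totals[0]
            or algo_table.totals[1] + n_bloody_wo != gbs_table.totals[1]):
        raise CohortError(
            "algorithm-table totals plus bloody counts do not match GBS-table totals"
        )

    bloody_w = gw - aw
    bloody_wo = gwo - awo
    if (bloody_w < 0).any() or (bloody_wo < 0).any():
        raise CohortError(
            "inconsistent tables: algorithm per-score count exceeds GBS count"
        )
    if bloody_w.sum() != n_bloody_w or bloody_wo.sum() != n_bloody_wo:
        raise CohortError("bloody counts do not match the table differences")

    if non_bloody_categories is not None:
        for hrel, (n_nb, counts) in zip(
            (True, False),
            ((int(aw.sum()), aw), (int(awo.sum()), awo)),
        ):
            if sum(non_bloody_categories[hrel]) != n_nb:
                raise CohortError(
                    "non-bloody category counts do not match the stratum size"
                )

    records: list[PatientRecord] = []

    def nb_category_stream(hrel: bool):
        if non_bloody_categories is None:
            while True:
                yield "clear"
        counts = non_bloody_categories[hrel]
        for cat, n in zip(NON_BLOODY, counts):
            for _ in range(n):
                yield cat

    def emit(n: int, gbs: int, bloody: bool, hrel: bool, nb_stream) -> None:
        for _ in range(n):
            records.append(PatientRecord(
                id=f"P{len(records) + 1:03d}",
                nga="bloody" if bloody else next(nb_stream),
                hrel=hrel,
                gbs=gbs,
            ))

    for hrel, counts_b, counts_nb in (
        (True, bloody_w, aw),
        (False, bloody_wo, awo),
    ):
        stream = nb_category_stream(hrel)
        for gbs in range(size):
            emit(int(counts_b[gbs]), gbs, True, hrel, stream)
        for gbs in range(size):
            emit(int(counts_nb[gbs]), gbs, False, hrel, stream)

    return records


def study_cohort_path() -> Path:
    """Path of the shipped reconstructed-cohort fixture CSV."""
    return _data_path("study_cohort.csv")


def study_cohort() -> list[PatientRecord]:
    """The 115-patient study cohort, reconstructed from the printed tables."""
    gbs_table, algo_table = study_tables()
    return reconstruct_cohort(
        gbs_table, algo_table,
        non_bloody_categories=STUDY_NON_BLOODY_CATEGORIES,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_BOOL_COLUMNS = {"hematemesis", "melena", "syncope", "hepatic_disease",
                 "cardiac_failure", "hrel"}
_FLOAT_COLUMNS = {"age", "sbp", "dbp", "pulse", "hemoglobin_g_dl", "bun_value"}


def _parse_cell(col: str, raw: str, row_ix: int):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if col in _BOOL_COLUMNS:
            if raw not in ("0", "1"):
                raise ValueError("booleans are coded 0/1")
            return raw == "1"
        if col in _FLOAT_COLUMNS:
            return float(raw)
        if col == "gbs":
            if float(raw) != int(float(raw)):
                raise ValueError("gbs must be an integer")
            return int(float(raw))
    except ValueError as exc:
        raise CohortError(f"row {row_ix}: column {col!r}: {exc}") from None
    return raw


def read_cohort(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a cohort CSV; rows violating record invariants raise row-indexed errors.

    ``columns`` optionally maps canonical column names to the names used in the
    file (e.g. ``{"gbs": "blatchford"}``).
    """
    columns = dict(columns or {})
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortError(f"{path}: empty file, header required")
        header = set(reader.fieldnames)
        for required in ("id", "nga", "hrel"):
            if columns.get(required, required) not in header:
                raise CohortError(f"{path}: missing required column {required!r}")
        records = []
        for row_ix, row in enumerate(reader, start=1):
            kwargs = {}
            for f in fields(PatientRecord):
                src = columns.get(f.name, f.name)
                if src in row and row[src] is not None:
                    kwargs[f.name] = _parse_cell(f.name, row[src], row_ix)
            if kwargs.get("hrel") is None:
                raise CohortError(f"row {row_ix}: hrel is required")
            try:
                records.append(PatientRecord(**kwargs))
            except CohortError as exc:
                raise CohortError(f"row {row_ix}: {exc}") from None
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records in the cohort CSV dialect (booleans as 0/1, blanks for None)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            row = []
            for col in CSV_COLUMNS:
                v = getattr(r, col)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append("1" if v else "0")
                elif isinstance(v, float):
                    row.append(f"{v:g}")
                else:
                    row.append(str(v))
            writer.writerow(row)


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-stratum (with / without HREL) summary of the cohort.

    Numeric fields get mean and SD (SD absent for n=1); categorical fields get
    n (%).  Percentages for NGA categories are out of the stratum size.
    """
    if not records:
        raise CohortError("summarize_cohort: empty cohort")
    df = pd.DataFrame([{
        "hrel": r.hrel, "nga": r.nga, "bloody": r.bloody, "gbs": r.gbs,
        "age": r.age, "sbp": r.sbp, "pulse": r.pulse,
    } for r in records])

    rows = []
    strata = {"total": df, "with_hrel": df[df.hrel], "without_hrel": df[~df.hrel]}
    for name, sub in strata.items():
        n = len(sub)
        row: dict[str, object] = {"stratum": name, "n": n}
        for num in ("gbs", "age", "sbp", "pulse"):
            vals = sub[num].dropna()
            row[f"{num}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{num}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else None
        for cat in NGA_CATEGORIES:
            c = int((sub.nga == cat).sum())
            row[f"nga_{cat}_n"] = c
            row[f"nga_{cat}_pct"] = 100.0 * c / n if n else None
        nb = int((~sub.bloody).sum())
        row["nga_non_bloody_n"] = nb
        row["nga_non_bloody_pct"] = 100.0 * nb / n if n else None
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
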