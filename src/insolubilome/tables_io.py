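"""Readers, writers and validated containers for the pipeline's table formats.

Every object the analysis touches enters through this module: protein-level
quantification matrices from DIA extraction (TSV), gene-set collections
(GMT), worm-to-human orthology maps (two-column TSV), the disease-to-GO-BP
catalog with broad disease categories, per-protein biophysical score tables,
and long-format aging expression series. Readers validate and reject
malformed input rather than coercing it; every writer produces a file its
paired reader parses back to an equal object.

Conventions: UTF-8, tab-separated, '.' decimal point, empty string = missing.
Sample columns of a quantification matrix are named ``<condition>:<pair>``
(e.g. ``case:1``, ``control:1``) where *condition* is ``case`` (the Aβ /
treatment arm) or ``control`` and *pair* indexes the biological replicate
pair the two samples share.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "CONDITIONS",
    "CARD_CATEGORIES",
    "NON_ARD_CATEGORY",
    "QuantMatrix",
    "GeneSet",
    "GeneSetCollection",
    "OrthologyMap",
    "DiseaseRecord",
    "DiseaseBPCatalog",
    "ScoreTable",
    "ExpressionSeries",
    "normalize_id",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_gmt",
    "write_gmt",
    "read_orthology",
    "write_orthology",
    "read_disease_catalog",
    "write_disease_catalog",
    "read_score_table",
    "write_score_table",
    "read_expression",
    "write_expression",
    "read_protein_list",
    "write_protein_list",
]


class TableFormatError(ValueError):
    """A file (or in-memory table) violates its documented schema."""


CONDITIONS = ("case", "control")

#: The five broad chronic age-related disease classes.
CARD_CATEGORIES = ("neurodegenerative", "metabolic", "cancer", "cardiovascular", "other")

#: Category label carried by diseases that are not age-related.
NON_ARD_CATEGORY = "non_ARD"

SCORE_COLUMNS = ("camsol", "zyggregator", "catgranule", "sigma_f")

_SAMPLE_TOKEN = re.compile(r"^(case|control):(\d+)$")
_ISOFORM_SUFFIX = re.compile(r"[a-z]$")


def normalize_id(identifier: str, *, casefold: bool = False, strip_isoform: bool = False) -> str:
    """Normalize a protein/gene identifier.

    ``casefold`` lower-cases the identifier; ``strip_isoform`` removes a
    single trailing lower-case splice-tag letter (``hsp-16.2a`` -> ``hsp-16.2``).
    Both default to off: the identifier space (WormBase names on the worm
    side, HGNC symbols on the human side) is taken as-is unless configured.
    """
    out = identifier.strip()
    if strip_isoform and len(out) > 1 and _ISOFORM_SUFFIX.search(out):
        out = out[:-1]
    if casefold:
        out = out.casefold()
    return out


# ---------------------------------------------------------------------------
# Quantification matrix
# ---------------------------------------------------------------------------

@dataclass
class QuantMatrix:
    """Protein x sample intensity table for one insoluble-fraction experiment.

    ``intensities`` is indexed by protein id with one column per sample
    (``case:1`` ... ``control:n``); NaN marks a missing quantification.
    ``unique_peptides`` counts unique peptides per protein group and feeds
    the >=2-peptide significance filter downstream.
    """

    intensities: pd.DataFrame
    unique_peptides: pd.Series

    def __post_init__(self) -> None:
        self.intensities.index.name = "protein_id"
        ids = self.intensities.index
        if ids.has_duplicates:
            dup = ids[ids.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate protein ids: {dup}")
        pairs: dict[str, set[int]] = {c: set() for c in CONDITIONS}
        for col in self.intensities.columns:
            m = _SAMPLE_TOKEN.match(str(col))
            if m is None:
                raise TableFormatError(
                    f"sample column {col!r} is not of the form condition:pair"
                )
            cond, idx = m.group(1), int(m.group(2))
            if idx in pairs[cond]:
                raise TableFormatError(f"pair index {idx} repeated for {cond}")
            pairs[cond].add(idx)
        if pairs["case"] != pairs["control"]:
            raise TableFormatError(
                f"unpaired samples: case pairs {sorted(pairs['case'])} vs "
                f"control pairs {sorted(pairs['control'])}"
            )
        if not pairs["case"]:
            raise TableFormatError("matrix has no sample columns")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise TableFormatError("negative intensity encountered")
        self.unique_peptides = self.unique_peptides.reindex(ids)
        if self.unique_peptides.isna().any():
            missing = self.unique_peptides.index[self.unique_peptides.isna()].tolist()
            raise TableFormatError(f"unique_peptides missing for: {missing[:5]}")
        self.unique_peptides = self.unique_peptides.astype(int)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def pair_indices(self) -> list[int]:
        idx = [
            int(_SAMPLE_TOKEN.match(str(c)).group(2))
            for c in self.intensities.columns
            if str(c).startswith("case:")
        ]
        return sorted(idx)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_indices)

    def condition_columns(self, condition: str) -> list[str]:
        """Sample columns of one condition, ordered by pair index."""
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        return [f"{condition}:{i}" for i in self.pair_indices]


def read_quant_matrix(path: str | Path) -> QuantMatrix:
    """Read a quantification matrix TSV.

    Expected columns: ``protein_id``, ``unique_peptides`` and one column per
    sample named ``condition:pair``. Empty cells are missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for required in ("protein_id", "unique_peptides"):
        if required not in df.columns:
            raise TableFormatError(f"{path}: missing required column {required!r}")
    sample_cols = [c for c in df.columns if c not in ("protein_id", "unique_peptides")]
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate protein id {dup.iloc[0]!r}")
    intens = df.set_index("protein_id")[sample_cols].astype(float)
    peptides = df.set_index("protein_id")["unique_peptides"]
    return QuantMatrix(intensities=intens, unique_peptides=peptides)


def write_quant_matrix(m: QuantMatrix, path: str | Path) -> None:
    out = m.intensities.copy()
    out.insert(0, "unique_peptides", m.unique_peptides)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """A namespace-tagged collection of gene sets (GO-BP, KEGG, ...)."""

    namespace: str
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, gs in self.sets.items():
            if term_id != gs.term_id:
                raise TableFormatError(f"key {term_id!r} != term id {gs.term_id!r}")
            if not gs.members:
                raise TableFormatError(f"term {term_id!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        """Invert the collection: gene id -> set of term ids annotating it."""
        out: dict[str, set[str]] = {}
        for gs in self.sets.values():
            for g in gs.members:
                out.setdefault(g, set()).add(gs.term_id)
        return {g: frozenset(ts) for g, ts in out.items()}


def read_gmt(path: str | Path, namespace: str = "GO-BP") -> GeneSetCollection:
    """Read a standard GMT file: term_id <tab> description <tab> members..."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, needs >=3"
                )
            term_id, name = parts[0], parts[1]
            members = frozenset(p for p in parts[2:] if p)
            if term_id in sets:
                raise TableFormatError(f"{path}:{lineno}: duplicate term {term_id!r}")
            sets[term_id] = GeneSet(term_id, name, members)
    return GeneSetCollection(namespace=namespace, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.sets.values():
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------

@dataclass
class OrthologyMap:
    """Many-to-many worm -> human identifier map."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for src, targets in self.mapping.items():
            if not targets:
                raise TableFormatError(f"orthology source {src!r} has no targets")

    def __len__(self) -> int:
        return len(self.mapping)

    def targets(self, source_id: str) -> frozenset[str]:
        return self.mapping.get(source_id, frozenset())


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a two-column TSV (source_id <tab> target_id), one edge per row."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and "\t" not in header:
            raise TableFormatError(f"{path}: expected two tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise TableFormatError(f"{path}:{lineno}: malformed orthology row {line!r}")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return OrthologyMap({s: frozenset(t) for s, t in mapping.items()})


def write_orthology(m: OrthologyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_id\ttarget_id\n")
        for src in sorted(m.mapping):
            for tgt in sorted(m.mapping[src]):
                fh.write(f"{src}\t{tgt}\n")


# ---------------------------------------------------------------------------
# Disease -> GO-BP catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    name: str
    category: str
    age_related: bool
    terms: frozenset[str]


@dataclass
class DiseaseBPCatalog:
    """GWAS-derived catalog mapping each disease to its risk GO-BP term set.

    Age-related diseases (CARDs) carry one of the five broad categories;
    non-age-related diseases carry the ``non_ARD`` label.
    """

    diseases: dict[str, DiseaseRecord]

    def __post_init__(self) -> None:
        for d in self.diseases.values():
            if not d.terms:
                raise TableFormatError(f"disease {d.disease_id!r} has no GO-BP terms")
            if d.age_related:
                if d.category not in CARD_CATEGORIES:
                    raise TableFormatError(
                        f"disease {d.disease_id!r}: unknown category {d.category!r}"
                    )
            elif d.category != NON_ARD_CATEGORY:
                raise TableFormatError(
                    f"non-age-related disease {d.disease_id!r} must use category "
                    f"{NON_ARD_CATEGORY!r}, got {d.category!r}"
                )

    @property
    def ard_ids(self) -> list[str]:
        return [d for d, r in self.diseases.items() if r.age_related]

    @property
    def nard_ids(self) -> list[str]:
        return [d for d, r in self.diseases.items() if not r.age_related]

    def counts(self) -> tuple[int, int]:
        """(number of age-related, number of non-age-related) diseases."""
        return len(self.ard_ids), len(self.nard_ids)


def read_disease_catalog(path: str | Path) -> DiseaseBPCatalog:
    """Read the disease catalog TSV.

    Columns: disease_id, name, category, age_related (0/1), terms
    (semicolon-separated GO-BP term ids).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "name", "category", "age_related", "terms"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    diseases: dict[str, DiseaseRecord] = {}
    for row in df.itertuples(index=False):
        if row.disease_id in diseases:
            raise TableFormatError(f"{path}: duplicate disease {row.disease_id!r}")
        terms = frozenset(t for t in str(row.terms).split(";") if t)
        diseases[row.disease_id] = DiseaseRecord(
            disease_id=row.disease_id,
            name=row.name,
            category=row.category,
            age_related=str(row.age_related).strip() in ("1", "true", "True"),
            terms=terms,
        )
    return DiseaseBPCatalog(diseases)


def write_disease_catalog(catalog: DiseaseBPCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tname\tcategory\tage_related\tterms\n")
        for d in catalog.diseases.values():
            fh.write(
                f"{d.disease_id}\t{d.name}\t{d.category}\t{int(d.age_related)}\t"
                + ";".join(sorted(d.terms))
                + "\n"
            )


# ---------------------------------------------------------------------------
# Biophysical score table
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Per-protein biophysical predictor scores.

    Columns: ``camsol`` (intrinsic solubility), ``zyggregator`` (aggregation
    propensity), ``catgranule`` (LLPS propensity) and ``sigma_f``
    (supersaturation, strictly positive on the linear scale; compare on
    log10 for display). Missing scores are NaN.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.scores.columns]
        if missing:
            raise TableFormatError(f"score table missing columns {missing}")
        if self.scores.index.has_duplicates:
            raise TableFormatError("duplicate protein ids in score table")
        sf = self.scores["sigma_f"]
        if (sf.dropna() <= 0).any():
            bad = sf.index[sf <= 0].tolist()
            raise TableFormatError(f"non-positive sigma_f for {bad[:5]}")

    def column(self, score_name: str) -> pd.Series:
        if score_name == "sigma_f_log10":
            return np.log10(self.scores["sigma_f"])
        if score_name not in SCORE_COLUMNS:
            raise KeyError(f"unknown score {score_name!r}")
        return self.scores[score_name]


def read_score_table(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise TableFormatError(f"{path}: missing protein_id column")
    return ScoreTable(df.set_index("protein_id").astype(float))


def write_score_table(t: ScoreTable, path: str | Path) -> None:
    out = t.scores.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Expression series
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSeries:
    """Long-format gene x age expression values, optionally multi-dataset."""

    values: pd.DataFrame  # columns: gene_id, age_day, value, dataset_id

    def __post_init__(self) -> None:
        required = {"gene_id", "age_day", "value", "dataset_id"}
        if not required.issubset(self.values.columns):
            raise TableFormatError(
                f"expression table missing columns {sorted(required - set(self.values.columns))}"
            )

    def window(self, day_min: int, day_max: int) -> "ExpressionSeries":
        sub = self.values[
            (self.values["age_day"] >= day_min) & (self.values["age_day"] <= day_max)
        ].reset_index(drop=True)
        return ExpressionSeries(sub)


def read_expression(path: str | Path) -> ExpressionSeries:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "dataset_id": str}
    )
    return ExpressionSeries(df)


def write_expression(e: ExpressionSeries, path: str | Path) -> None:
    e.values.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plain protein lists
# ---------------------------------------------------------------------------

def read_protein_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_protein_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in sorted(set(ids)):
            fh.write(i + "\n")
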