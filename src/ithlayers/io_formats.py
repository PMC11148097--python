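"""Readers/writers for every external table the pipeline touches, plus the
cohort bundle that ties them together.

Formats (all tab-separated with a fixed header row; unknown extra columns
are preserved on read but ignored):

* samples — patient_id, region_id, tissue{tumor,normal}, purity,
  mean_depth, qscore, contamination
* mutations (MAF-like; 1-based inclusive positions) — patient_id,
  region_id, chrom, pos, ref, alt, gene, variant_class, alt_reads,
  ref_reads, pop_freq, driver_role
* segments (SEG-like; 0-based half-open) — region_id, chrom, start, end,
  state{amp,del,neutral}, arm
* methylation (BED-like; 0-based half-open) — region_id, chrom, start,
  end, methylated_count, total_count
* expression — genes × regions non-negative abundance matrix
* clinical — patient_id, subtype{H,L}, purity_class, stage, os_months,
  os_event, rfs_months, rfs_event

Trees are serialized as Newick; the pipeline report is JSON with sorted
keys and full float precision so fixed-seed runs diff byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from .phylo_trees import PhyloTree

__all__ = [
    "RegionSample",
    "CohortBundle",
    "ReferentialIntegrityError",
    "TableParseError",
    "load_cohort",
    "write_cohort",
    "write_newick",
    "read_newick",
    "write_report",
    "read_report",
]


class ReferentialIntegrityError(ValueError):
    """A table row references a patient/region absent from the sample sheet."""


class TableParseError(ValueError):
    """A table cell could not be parsed as its declared type."""


SAMPLE_SCHEMA = {
    "patient_id": str,
    "region_id": str,
    "tissue": str,
    "purity": float,
    "mean_depth": float,
    "qscore": float,
    "contamination": float,
}
MUTATION_SCHEMA = {
    "patient_id": str,
    "region_id": str,
    "chrom": str,
    "pos": int,
    "ref": str,
    "alt": str,
    "gene": str,
    "variant_class": str,
    "alt_reads": int,
    "ref_reads": int,
    "pop_freq": float,
    "driver_role": str,
}
SEGMENT_SCHEMA = {
    "region_id": str,
    "chrom": str,
    "start": int,
    "end": int,
    "state": str,
    "arm": str,
}
METHYLATION_SCHEMA = {
    "region_id": str,
    "chrom": str,
    "start": int,
    "end": int,
    "methylated_count": int,
    "total_count": int,
}
CLINICAL_SCHEMA = {
    "patient_id": str,
    "subtype": str,
    "purity_class": str,
    "stage": str,
    "os_months": float,
    "os_event": int,
    "rfs_months": float,
    "rfs_event": int,
}

_TABLE_SCHEMAS = {
    "samples": SAMPLE_SCHEMA,
    "mutations": MUTATION_SCHEMA,
    "segments": SEGMENT_SCHEMA,
    "methylation": METHYLATION_SCHEMA,
    "clinical": CLINICAL_SCHEMA,
}


@dataclass(frozen=True)
class RegionSample:
    """One sampled region: a spatially separated tumor piece or the matched
    normal of a patient."""

    patient_id: str
    region_id: str
    tissue: str  # tumor | normal
    purity: float
    mean_depth: float
    qscore: float
    contamination: float

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor|normal, got {self.tissue!r}")
        if self.tissue == "tumor" and not 0.0 < self.purity <= 1.0:
            raise ValueError(f"tumor purity must be in (0, 1], got {self.purity}")


@dataclass
class CohortBundle:
    """All per-layer tables of a cohort, cross-referenced against the
    sample sheet.  Absent optional layers are empty frames."""

    samples: pd.DataFrame
    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for name in _TABLE_SCHEMAS:
            df = getattr(self, name)
            if df is None or (hasattr(df, "empty") and df.empty):
                setattr(self, name, _empty_table(name))

    def validate(self) -> None:
        regions = set(self.samples["region_id"])
        patients = set(self.samples["patient_id"])
        for name in ("mutations", "segments", "methylation"):
            df = getattr(self, name)
            if df.empty:
                continue
            bad = sorted(set(df["region_id"]) - regions)
            if bad:
                raise ReferentialIntegrityError(
                    f"{name} table references unknown region(s) {bad}"
                )
        if not self.expression.empty:
            bad = sorted(set(map(str, self.expression.columns)) - regions)
            if bad:
                raise ReferentialIntegrityError(
                    f"expression matrix references unknown region(s) {bad}"
                )
        if not self.clinical.empty:
            bad = sorted(set(self.clinical["patient_id"]) - patients)
            if bad:
                raise ReferentialIntegrityError(
                    f"clinical table references unknown patient(s) {bad}"
                )

    def tumor_regions(self, patient_id: str) -> list[str]:
        s = self.samples
        mask = (s["patient_id"] == patient_id) & (s["tissue"] == "tumor")
        return sorted(s.loc[mask, "region_id"])

    def normal_region(self, patient_id: str) -> str | None:
        s = self.samples
        mask = (s["patient_id"] == patient_id) & (s["tissue"] == "normal")
        hits = sorted(s.loc[mask, "region_id"])
        return hits[0] if hits else None

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.samples["patient_id"].unique())


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _TABLE_SCHEMAS[name].items()})


def _read_table(path: Path, schema: dict) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame(index=df.index)
    for col, typ in schema.items():
        raw = df[col]
        if typ is str:
            out[col] = raw.astype(str)
            continue
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise TableParseError(
                f"{path}, line {line}: cannot parse {col}={raw[bad.idxmax()]!r} as {typ.__name__}"
            )
        out[col] = converted.astype(float if typ is float else "int64")
    return out


def _read_expression(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        col = mat.columns[mat.isna().any()][0]
        raise TableParseError(f"{path}: non-numeric abundance in column {col!r}")
    if (mat < 0).any().any():
        raise TableParseError(f"{path}: negative abundance value")
    mat.columns = mat.columns.astype(str)
    return mat


def load_cohort(manifest: str | Path) -> CohortBundle:
    """Load and cross-validate a cohort from a YAML manifest.

    The manifest maps layer names (samples, mutations, segments,
    methylation, expression, clinical) to TSV paths relative to the
    manifest's directory.  The sample sheet is mandatory; other layers may
    be absent and then yield empty tables.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        doc = yaml.safe_load(fh) or {}
    tables = doc.get("tables", doc)
    base = manifest.parent

    def path_of(name: str) -> Path | None:
        rel = tables.get(name)
        return None if rel is None else base / rel

    sample_path = path_of("samples")
    if sample_path is None:
        raise TableParseError(f"{manifest}: manifest must name a samples table")
    kwargs: dict = {"samples": _read_table(sample_path, SAMPLE_SCHEMA)}
    for name in ("mutations", "segments", "methylation", "clinical"):
        p = path_of(name)
        kwargs[name] = _read_table(p, _TABLE_SCHEMAS[name]) if p else _empty_table(name)
    expr_path = path_of("expression")
    kwargs["expression"] = _read_expression(expr_path) if expr_path else pd.DataFrame()
    bundle = CohortBundle(**kwargs)
    bundle.validate()
    return bundle


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Write every table of a bundle as TSV plus a manifest.yaml; returns
    the manifest path.  Round trip through :func:`load_cohort` is the
    identity."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, str] = {}
    for name in _TABLE_SCHEMAS:
        df = getattr(bundle, name)
        fname = f"{name}.tsv"
        df.to_csv(outdir / fname, sep="\t", index=False)
        tables[name] = fname
    if not bundle.expression.empty:
        bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
        tables["expression"] = "expression.tsv"
    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"tables": tables}, fh, sort_keys=True)
    return manifest


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to a Newick string with branch lengths.

    Requires >= 2 leaves, every leaf named, and finite non-negative edge
    lengths; re-parsing reproduces topology and lengths."""
    if len(tree.leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    for leaf in tree.leaves:
        if not str(leaf):
            raise ValueError("unnamed leaf")
    for u, v, w in tree.edges:
        if not math.isfinite(w) or w < 0:
            raise ValueError(f"edge {u}-{v} has invalid length {w}")
    return tree.to_newick()


def read_newick(newick: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree` (internal nodes are
    renamed ``_i1``, ``_i2``, ...)."""
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    counter = 0
    names: dict = {}

    def name_of(node) -> str:
        nonlocal counter
        if node.taxon is not None:
            return node.taxon.label
        if node not in names:
            counter += 1
            names[node] = f"_i{counter}"
        return names[node]

    edges = []
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append(
                (name_of(node), name_of(child), float(child.edge.length or 0.0))
            )
    return PhyloTree.from_edges(edges)


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(results: dict, path: str | Path) -> None:
    """Write the machine-readable pipeline report as JSON with sorted keys
    and full float precision (repr round trip)."""
    if not results:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
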