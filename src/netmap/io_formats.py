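"""Readers, writers and validated containers for every file the pipeline touches.

Formats are plain text throughout: two-column or BioGRID TAB2-style edge lists
for the interactome, GMT for gene-set annotations, TSV for spot-volume tables
and cohort tables, GraphML plus edge-list TSV for network export. Tables use
tab separation, UTF-8 and '.' decimals.

Gene symbols are uppercased on ingest so that case variants of the same symbol
(e.g. "Co4" vs "CO4") cannot silently become distinct network nodes.
Self-interactions are dropped (the modularity and betweenness definitions used
downstream assume simple graphs); the dropped count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

AIS_GRADES = frozenset("ABCD")

#: Dye orientation labels: which severity group received which Cy dye on a gel.
COMPLETE_CY5 = "complete_cy5"  # complete-injury (AIS A) sample labelled Cy5
COMPLETE_CY3 = "complete_cy3"  # reverse-labelled gel: complete sample got Cy3
DYE_ORIENTATIONS = frozenset({COMPLETE_CY5, COMPLETE_CY3})

#: 0-based column indices of the official-symbol columns in BioGRID TAB2 files.
TAB2_SYMBOL_COLS = (7, 8)

COHORT_COLUMNS = [
    "age",
    "sensory_level",
    "motor_level",
    "days_post_injury",
    "dige_pair",
    "ais_grade",
    "cause",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in canonical (min, max) order, uppercased."""
    a, b = a.strip().upper(), b.strip().upper()
    return (a, b) if a <= b else (b, a)


@dataclass
class Interactome:
    """An undirected background interaction network over gene symbols.

    ``pairs`` holds canonical (min, max) symbol tuples: no self-pairs, no
    duplicates, symbols non-empty and uppercase.
    """

    pairs: frozenset[tuple[str, str]]
    source_meta: str | None = None

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   source_meta: str | None = None) -> "Interactome":
        """Build from raw symbol pairs, applying the dedupe/self-loop/case rules."""
        pairs: set[tuple[str, str]] = set()
        n_self = 0
        for a, b in edges:
            a, b = str(a).strip().upper(), str(b).strip().upper()
            if not a or not b:
                raise FormatError("empty gene symbol in interaction pair")
            if a == b:
                n_self += 1
                continue
            pairs.add((a, b) if a <= b else (b, a))
        if n_self:
            logger.info("dropped %d self-interaction(s)", n_self)
        return cls(pairs=frozenset(pairs), source_meta=source_meta)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(s for p in self.pairs for s in p)

    def partners(self, symbol: str) -> frozenset[str]:
        """Direct interaction partners of ``symbol`` (empty if unlisted)."""
        symbol = symbol.upper()
        return frozenset(b if a == symbol else a
                         for a, b in self.pairs if symbol in (a, b))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.pairs)
        return g

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationSet:
    """Flat gene-set annotations (GO / KEGG style) plus the universe size N.

    ``universe_size`` is the total number of genes in the organism against
    which over-representation is judged; a GMT file cannot know it without a
    directive, so it defaults to the size of the union of all annotated genes.
    """

    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    universe_size: int = 0

    def __post_init__(self) -> None:
        union: set[str] = set()
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise InvalidParameterError(f"term {term!r} has an empty gene set")
            union |= genes
        if self.universe_size == 0:
            self.universe_size = len(union)
        if self.universe_size < len(union):
            raise InvalidParameterError(
                f"universe_size {self.universe_size} smaller than the "
                f"{len(union)} annotated genes")

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(g for gs in self.term_to_genes.values() for g in gs)


@dataclass
class CohortTable:
    """Clinical cohort rows: age, injury levels, days post injury, DIGE pairing,
    AIS grade and cause of injury."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"cohort table missing column(s): {missing}")
        if (self.df["age"] <= 0).any():
            raise FormatError("cohort ages must be positive")
        if (self.df["days_post_injury"] < 0).any():
            raise FormatError("days_post_injury must be non-negative")
        bad = set(self.df["ais_grade"]) - AIS_GRADES
        if bad:
            raise FormatError(f"unknown AIS grade(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GelRecord:
    """One DIGE gel: its dye orientation and the Cy5/Cy3 spot volume ratios."""

    gel_id: str
    dye_orientation: str
    spot_ratios: dict[str, float]

    def __post_init__(self) -> None:
        if self.dye_orientation not in DYE_ORIENTATIONS:
            raise FormatError(
                f"gel {self.gel_id}: unknown dye orientation "
                f"{self.dye_orientation!r} (expected one of {sorted(DYE_ORIENTATIONS)})")
        for spot, r in self.spot_ratios.items():
            if not r > 0:
                raise FormatError(f"gel {self.gel_id} spot {spot}: ratio {r} not positive")


@dataclass
class DigeExperiment:
    """A set of DIGE gels plus the spot → protein identification map.

    A spot may be absent from some gels (failed matching); a spot may carry
    several identified proteins (comigration), and one protein may occupy
    several spots (isoforms).
    """

    gels: list[GelRecord]
    spot_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def spot_ids(self) -> frozenset[str]:
        return frozenset(s for g in self.gels for s in g.spot_ratios)


# ---------------------------------------------------------------------------
# interactome

def read_interactome(path: str | Path, dialect: str = "two-column",
                     symbol_cols: tuple[int, int] = TAB2_SYMBOL_COLS) -> Interactome:
    """Read an interactome edge list.

    dialect "two-column": each non-comment line is ``SYMBOL_A<TAB>SYMBOL_B``.
    dialect "tab2-like": BioGRID TAB2-style TSV; only the official-symbol
    columns (``symbol_cols``, 0-based) are consumed.
    """
    path = Path(path)
    if dialect not in ("two-column", "tab2-like"):
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "two-column":
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise FormatError(f"{path}:{lineno}: expected two tab-separated symbols")
                a, b = fields[0], fields[1]
            else:
                ia, ib = symbol_cols
                if len(fields) <= max(ia, ib):
                    raise FormatError(
                        f"{path}:{lineno}: fewer than {max(ia, ib) + 1} columns")
                a, b = fields[ia], fields[ib]
                if not a.strip() or not b.strip():
                    raise FormatError(f"{path}:{lineno}: empty symbol field")
            edges.append((a, b))
    if not edges:
        raise FormatError(f"{path}: no interactions found")
    return Interactome.from_edges(edges, source_meta=str(path))


def write_interactome(inter: Interactome, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in sorted(inter.pairs):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT annotations

def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT gene-set file: ``term<TAB>description<TAB>gene...`` per line.

    A directive line ``#universe=<int>`` before the first record sets the
    universe size N; otherwise N defaults to the union of annotated genes,
    with a logged warning.
    """
    path = Path(path)
    term_to_genes: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    universe = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                directive = line[1:].strip()
                if directive.lower().startswith("universe"):
                    try:
                        universe = int(directive.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise FormatError(
                            f"{path}:{lineno}: bad universe directive {line!r}") from exc
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene")
            term, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            term_to_genes[term] = genes
            term_names[term] = desc
    if universe == 0:
        logger.warning("%s: no universe directive; defaulting N to the union "
                       "of annotated genes", path)
    return AnnotationSet(term_to_genes=term_to_genes, term_names=term_names,
                         universe_size=universe)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#universe={annotations.universe_size}\n")
        for term in sorted(annotations.term_to_genes):
            desc = annotations.term_names.get(term, term)
            genes = "\t".join(sorted(annotations.term_to_genes[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"dige_pair": str})
    try:
        df["age"] = df["age"].astype(int)
        df["days_post_injury"] = df["days_post_injury"].astype(int)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return CohortTable(df=df[COHORT_COLUMNS].copy())


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DIGE spot tables

def read_spot_table(path: str | Path,
                    spot_map_path: str | Path | None = None) -> DigeExperiment:
    """Read a long-format spot-ratio TSV: gel_id, dye_orientation, spot_id, ratio.

    A spot missing from a gel is simply absent from that gel's rows.
    Optionally reads a spot map TSV (spot_id, protein_name, gene_symbol).
    """
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "gel_id": str})
    required = {"gel_id", "dye_orientation", "spot_id", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    gels = []
    for gel_id, sub in df.groupby("gel_id", sort=True):
        orientations = set(sub["dye_orientation"])
        if len(orientations) != 1:
            raise FormatError(f"{path}: gel {gel_id} has conflicting dye orientations")
        gels.append(GelRecord(gel_id=str(gel_id),
                              dye_orientation=orientations.pop(),
                              spot_ratios=dict(zip(sub["spot_id"], sub["ratio"]))))
    spot_map: dict[str, list[tuple[str, str]]] = {}
    if spot_map_path is not None:
        spot_map = read_spot_map(spot_map_path)
    return DigeExperiment(gels=gels, spot_map=spot_map)


def read_spot_map(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"spot_id", "protein_name", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    spot_map: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        spot_map.setdefault(str(row.spot_id), []).append(
            (row.protein_name, row.gene_symbol.upper()))
    return spot_map


def write_spot_table(experiment: DigeExperiment, path: str | Path,
                     spot_map_path: str | Path | None = None) -> None:
    rows = [
        {"gel_id": g.gel_id, "dye_orientation": g.dye_orientation,
         "spot_id": spot, "ratio": ratio}
        for g in experiment.gels for spot, ratio in sorted(g.spot_ratios.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if spot_map_path is not None:
        map_rows = [
            {"spot_id": spot, "protein_name": name, "gene_symbol": gene}
            for spot, entries in sorted(experiment.spot_map.items())
            for name, gene in entries
        ]
        pd.DataFrame(map_rows, columns=["spot_id", "protein_name", "gene_symbol"]
                     ).to_csv(spot_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network / module / enrichment output

def write_network(graph: nx.Graph, graphml_path: str | Path,
                  edgelist_path: str | Path | None = None) -> None:
    """Export a network as GraphML (node attributes preserved) and, optionally,
    as an edge-list TSV with a per-node seed-flag column."""
    nx.write_graphml(graph, str(graphml_path))
    if edgelist_path is not None:
        with Path(edgelist_path).open("w", encoding="utf-8") as fh:
            fh.write("symbol_a\tsymbol_b\tseed_a\tseed_b\n")
            for a, b in sorted(canonical_pair(u, v) for u, v in graph.edges):
                fh.write(f"{a}\t{b}\t{int(graph.nodes[a].get('seed', False))}"
                         f"\t{int(graph.nodes[b].get('seed', False))}\n")


def write_modules(assignment: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node\tmodule_id\n")
        for node in sorted(assignment):
            fh.write(f"{node}\t{assignment[node]}\n")


def read_modules(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "module_id": int})
    return dict(zip(df["node"], df["module_id"]))


ENRICHMENT_COLUMNS = ["module_id", "term_id", "k", "n", "K", "N",
                      "hyp", "hyp_star", "significant"]


def write_enrichment(results: Sequence, path: str | Path) -> None:
    """Write enrichment rows (module, term, k, n, K, N, Hyp, Hyp*, significant)."""
    rows = [{c: getattr(r, c) for c in ENRICHMENT_COLUMNS} for r in results]
    pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS).to_csv(path, sep="\t", index=False)
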