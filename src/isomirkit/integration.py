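"""Joining DE miRs/isomiRs with DE genes and TF regulations.

Three layers are combined here:

* score-filtered target predictions (regulator -> gene, 0-100 confidence),
* differential-expression calls on both the small-RNA and the mRNA side,
* literature-curated TF -> miR-family regulations.

"Correlation" between a regulator and a target is the sign relation of
their fold changes: a pair is *negative* when the two log2 fold changes
have opposite signs.  Negative pairs are the functional, repression-
consistent set and are the only ones wired into the regulatory circuit;
positive pairs are reported but not wired.

Because all variants of one mature arm are transcribed from the same MIR
gene, a TF regulation recorded at family level applies to every DE variant
of that family.  Conversely a 3'-only variant keeps its parent's seed and
therefore inherits the parent's predicted targets when it has no
prediction rows of its own; 5'-shifted variants never inherit.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .isoclass import parse_name

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ["regulator", "gene", "score"]
TF_COLUMNS = ["tf", "mir_family", "direction", "literature_curated"]
PAIR_COLUMNS = ["regulator", "gene", "regulator_lfc", "gene_lfc", "klass"]


class IntegrationError(ValueError):
    pass


def family_of(name: str) -> str:
    """MIR-gene family of a canonical name: parent arm minus the -5p/-3p label."""
    parent = parse_name(name).parent
    if parent.endswith(("-5p", "-3p")):
        return parent[:-3]
    return parent


def filter_targets(targets: pd.DataFrame, min_score: float = 80.0) -> pd.DataFrame:
    """Keep predictions with score >= min_score (inclusive boundary)."""
    missing = [c for c in TARGET_COLUMNS if c not in targets.columns]
    if missing:
        raise IntegrationError(f"target table missing columns {missing}")
    scores = targets["score"].astype(float)
    if ((scores < 0) | (scores > 100)).any():
        bad = targets.loc[(scores < 0) | (scores > 100)].iloc[0]
        raise IntegrationError(
            f"target score out of range [0, 100]: {bad['regulator']} -> "
            f"{bad['gene']} score {bad['score']}"
        )
    return targets[scores >= min_score].reset_index(drop=True)


def _effective_targets(feature: str, by_regulator: dict[str, pd.DataFrame]) -> pd.DataFrame | None:
    """Target rows for a DE feature, with seed-aware parent inheritance."""
    own = by_regulator.get(feature)
    if own is not None and len(own):
        return own
    parsed = parse_name(feature)
    if parsed.category != "refseq" and parsed.offset5 == 0:
        return by_regulator.get(parsed.parent)
    return None


def pair_de(
    mir_de: pd.DataFrame, gene_de: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """Sign-correlated (regulator, gene) pairs among DE features.

    ``mir_de`` and ``gene_de`` are DE subsets (from ``call_de``) indexed by
    feature/gene with a ``log2fc`` column; ``targets`` is an already
    score-filtered prediction table.  One pair is emitted per (regulator,
    gene) with both sides DE, ordered lexicographically.
    """
    by_regulator = {k: v for k, v in targets.groupby("regulator")}
    gene_lfc = gene_de["log2fc"]
    rows = []
    for feature in mir_de.index:
        feat_targets = _effective_targets(feature, by_regulator)
        if feat_targets is None:
            continue
        reg_lfc = float(mir_de.loc[feature, "log2fc"])
        for gene in feat_targets["gene"].unique():
            if gene not in gene_lfc.index:
                continue
            g_lfc = float(gene_lfc.loc[gene])
            product = reg_lfc * g_lfc
            if product == 0.0:
                logger.warning(
                    "pair %s -> %s has a zero fold-change product; "
                    "classing as positive", feature, gene,
                )
            klass = "negative" if product < 0 else "positive"
            rows.append((feature, gene, reg_lfc, g_lfc, klass))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs.sort_values(["regulator", "gene"], kind="mergesort").reset_index(drop=True)


def multi_target_genes(
    pairs: pd.DataFrame | Iterable[tuple[str, str]],
) -> pd.Series:
    """Per-gene count of distinct regulators among negative pairs.

    Accepts a pairs table from :func:`pair_de` (only ``klass == negative``
    rows are counted) or a plain iterable of (regulator, gene) tuples that
    are already known to be negative pairs.  The multi-targeted subset is
    the ``count >= 2`` slice of the result.
    """
    if isinstance(pairs, pd.DataFrame):
        neg = pairs[pairs["klass"] == "negative"]
        tuples = list(zip(neg["regulator"], neg["gene"]))
    else:
        tuples = list(pairs)
    frame = pd.DataFrame(tuples, columns=["regulator", "gene"]).drop_duplicates()
    counts = frame.groupby("gene")["regulator"].nunique().sort_index()
    counts.name = "n_regulators"
    return counts


def expand_tf_regulations(
    regulations: pd.DataFrame,
    de_features: Sequence[str],
    curated_only: bool = True,
) -> list[tuple[str, str]]:
    """Expand family-level TF regulations to every DE variant of the family.

    Returns sorted (tf, feature) edges.  By default only literature-curated
    regulation records are used.
    """
    missing = [c for c in TF_COLUMNS if c not in regulations.columns]
    if missing:
        raise IntegrationError(f"TF table missing columns {missing}")
    regs = regulations
    if curated_only:
        curated = regs["literature_curated"].astype(bool)
        regs = regs[curated]

    def norm_family(fam: str) -> str:
        return fam[:-3] if fam.endswith(("-5p", "-3p")) else fam

    feature_families = {feat: family_of(feat) for feat in de_features}
    edges = set()
    for _, row in regs.iterrows():
        fam = norm_family(str(row["mir_family"]))
        for feat, feat_fam in feature_families.items():
            if feat_fam == fam:
                edges.add((str(row["tf"]), feat))
    return sorted(edges)


def build_circuit(
    pairs: pd.DataFrame,
    tf_edges: Iterable[tuple[str, str]],
    de_tf_genes: Sequence[str],
) -> nx.DiGraph:
    """Assemble the TF -> miR/isomiR-family -> gene regulatory circuit.

    Nodes are typed ``TF``, ``mir_family`` (isomiR variants collapsed to
    their parent arm, with the collapsed multiplicity recorded), and
    ``gene``.  ``mir_targets_gene`` edges come from negative pairs only;
    ``tf_regulates_mir`` edges from the expanded TF regulations.  No edge is
    invented: every edge maps back to an input relation.
    """
    de_tfs = set(de_tf_genes)
    graph = nx.DiGraph()

    def add_family(feature: str) -> str:
        fam_node = parse_name(feature).parent
        if graph.has_node(fam_node) and graph.nodes[fam_node]["kind"] == "mir_family":
            members = graph.nodes[fam_node]["members"]
        else:
            members = set()
            graph.add_node(fam_node, kind="mir_family", members=members)
        members.add(feature)
        graph.nodes[fam_node]["multiplicity"] = len(members)
        return fam_node

    def add_gene(gene: str) -> str:
        kind = "TF" if gene in de_tfs else "gene"
        graph.add_node(gene, kind=kind)
        return gene

    for _, row in pairs[pairs["klass"] == "negative"].iterrows():
        fam_node = add_family(row["regulator"])
        gene_node = add_gene(row["gene"])
        if gene_node == fam_node:
            raise IntegrationError(
                f"self-loop: miR family node {fam_node!r} targeted as a gene"
            )
        graph.add_edge(fam_node, gene_node, edge_type="mir_targets_gene")
    for tf, feature in tf_edges:
        fam_node = add_family(feature)
        graph.add_node(tf, kind="TF")
        graph.add_edge(tf, fam_node, edge_type="tf_regulates_mir")
    return graph


def compare_sets(
    a: Iterable[str], b: Iterable[str]
) -> tuple[list[str], list[str], list[str]]:
    """Partition two name lists into (only_a, only_b, shared), sorted."""
    sa, sb = set(a), set(b)
    return sorted(sa - sb), sorted(sb - sa), sorted(sa & sb)


def read_targets(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TARGET_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrationError(f"target table {path}: missing columns {missing}")
    return table


def read_tf_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TF_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrationError(f"TF table {path}: missing columns {missing}")
    return table


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_circuit_edges(graph: nx.DiGraph, path: str | Path) -> None:
    """Edge-list TSV export (src, dst, edge_type), lexicographically sorted."""
    rows = sorted(
        (src, dst, data["edge_type"]) for src, dst, data in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["src", "dst", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


def write_circuit_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal Graphviz DOT export with node kinds as shapes."""
    shapes = {"TF": "box", "mir_family": "ellipse", "gene": "plaintext"}
    with open(path, "w") as handle:
        handle.write("digraph circuit {\n")
        for node in sorted(graph.nodes):
            kind = graph.nodes[node].get("kind", "gene")
            handle.write(f'  "{node}" [shape={shapes[kind]}, kind={kind}];\n')
        for src, dst, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
            style = "solid" if data["edge_type"] == "tf_regulates_mir" else "dashed"
            handle.write(
                f'  "{src}" -> "{dst}" [label="{data["edge_type"]}", style={style}];\n'
            )
        handle.write("}\n")
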