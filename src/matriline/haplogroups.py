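"""Hierarchical diagnostic-motif haplogroup classification.

Haplogroups are nodes of a rooted tree; each node carries the
substitution motifs diagnostic for its branch *beyond its parent*. A
sample is assigned to the deepest node whose cumulative root-to-node
motif set is fully contained in the sample's variant set. Ties between
equally deep satisfied nodes yield ``unclassified`` with the tied
candidates reported; back-mutation at a diagnostic site therefore makes
the sample fall back to the deepest still-satisfied ancestor.

The bundled scheme (``data/cdv_scheme.yaml``) encodes the standard
A-I/V-Z chicken control-region nomenclature around the macrohaplogroup
CDV: the published motif sets for V ({A281G, T355C, C363T} cumulative),
V2 (V plus {C228T, A237G, C391T}) and D1b ({A281G, C296T, T306C, A342G,
G686A} cumulative) are encoded exactly; the remaining nodes carry
synthetic placeholder motifs (marked ``source: synthetic-placeholder``)
because their defining tables are distributed outside the main text —
the classifier is config-driven, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .seqio import VariantSet, parse_token

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    motifs: tuple[str, ...]  # diagnostic tokens beyond the parent
    source: str = ""


@dataclass
class MotifTree:
    """Validated rooted haplogroup tree with cumulative motif paths."""

    nodes: dict[str, HaplogroupNode]
    root: str
    children: dict[str, list[str]] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    cumulative: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.children = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                self.children[node.parent].append(node.name)
        for kids in self.children.values():
            kids.sort()
        # BFS from root: depths and cumulative motif paths
        self.depth = {self.root: 0}
        self.cumulative = {self.root: frozenset(self.nodes[self.root].motifs)}
        queue = [self.root]
        seen = {self.root}
        while queue:
            name = queue.pop(0)
            for child in self.children[name]:
                self.depth[child] = self.depth[name] + 1
                self.cumulative[child] = self.cumulative[name] | frozenset(
                    self.nodes[child].motifs
                )
                seen.add(child)
                queue.append(child)
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise ValueError(f"nodes unreachable from root: {sorted(unreachable)}")

    def path_to_root(self, name: str) -> list[str]:
        path = [name]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    haplogroup: str
    matched_path: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()


def load_motif_tree(config: str | Path | list[dict]) -> MotifTree:
    """Load and validate a motif tree from YAML/JSON config.

    The config is a list of mappings with fields ``name``, ``parent``
    (null for the root) and ``motifs`` (list of tokens). Tokens are
    syntax-checked at load; malformed tokens, duplicate names and
    unknown parents raise with the offending entry's index.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            entries = yaml.safe_load(fh)
    else:
        entries = config
    if not isinstance(entries, list) or not entries:
        raise ValueError("motif tree config must be a non-empty list of nodes")

    nodes: dict[str, HaplogroupNode] = {}
    roots: list[str] = []
    for i, entry in enumerate(entries, start=1):
        try:
            name = str(entry["name"])
            parent = entry.get("parent")
            parent = None if parent in (None, "", "null") else str(parent)
            motifs = tuple(parse_token(t).token for t in entry.get("motifs", []))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"motif tree config entry {i}: {exc}") from exc
        if name in nodes:
            raise ValueError(f"motif tree config entry {i}: duplicate node {name!r}")
        nodes[name] = HaplogroupNode(
            name=name, parent=parent, motifs=motifs, source=str(entry.get("source", ""))
        )
        if parent is None:
            roots.append(name)
    if len(roots) != 1:
        raise ValueError(f"motif tree must have exactly one root, found {roots}")
    for name, node in nodes.items():
        if node.parent is not None and node.parent not in nodes:
            raise ValueError(f"node {name!r}: unknown parent {node.parent!r}")
    return MotifTree(nodes=nodes, root=roots[0])


def default_motif_tree() -> MotifTree:
    """The bundled macrohaplogroup-CDV classification scheme."""
    with resources.as_file(resources.files("matriline.data") / "cdv_scheme.yaml") as p:
        return load_motif_tree(p)


def classify(vs: VariantSet, tree: MotifTree) -> ClassificationResult:
    """Assign a variant set to the deepest satisfied haplogroup node.

    A node is satisfied when its cumulative motif path is contained in
    the sample's tokens. Among equally deep satisfied nodes the result
    is ``unclassified`` with the candidates listed in ``conflicts``.
    ``missing`` lists the children's tokens that blocked deeper
    assignment; ``conflicts`` otherwise lists tokens present in the
    sample that are diagnostic for branches off the assigned path.
    """
    tokens = vs.tokens
    satisfied = [n for n in tree.nodes if tree.cumulative[n] <= tokens]
    if not satisfied:
        # root itself carries motifs the sample lacks
        return ClassificationResult(
            sample_id=vs.sample_id,
            haplogroup=UNCLASSIFIED,
            missing=tuple(sorted(tree.cumulative[tree.root] - tokens)),
        )
    max_depth = max(tree.depth[n] for n in satisfied)
    deepest = sorted(n for n in satisfied if tree.depth[n] == max_depth)
    if len(deepest) > 1:
        return ClassificationResult(
            sample_id=vs.sample_id,
            haplogroup=UNCLASSIFIED,
            matched_path=tuple(sorted(set().union(*(tree.cumulative[n] for n in deepest)) & tokens)),
            conflicts=tuple(deepest),
        )
    assigned = deepest[0]
    missing = sorted(
        set().union(
            *(frozenset(tree.nodes[c].motifs) - tokens for c in tree.children[assigned]),
            frozenset(),
        )
    )
    on_path = set(tree.path_to_root(assigned))
    off_path_tokens = set()
    for name, node in tree.nodes.items():
        if name not in on_path:
            off_path_tokens.update(node.motifs)
    conflicts = sorted((off_path_tokens - tree.cumulative[assigned]) & tokens)
    return ClassificationResult(
        sample_id=vs.sample_id,
        haplogroup=assigned,
        matched_path=tuple(sorted(tree.cumulative[assigned])),
        missing=tuple(missing),
        conflicts=tuple(conflicts),
    )


def haplogroup_frequencies(
    results: list[ClassificationResult], popmap: pd.DataFrame
) -> pd.DataFrame:
    """Population x haplogroup counts and within-population percentages.

    ``popmap`` must carry ``sample_id`` and ``population`` columns.
    Returns a tidy frame with columns population, haplogroup, count,
    percent; counts per population sum to the population sample size.
    """
    assign = pd.DataFrame(
        {"sample_id": [r.sample_id for r in results], "haplogroup": [r.haplogroup for r in results]}
    )
    merged = assign.merge(popmap[["sample_id", "population"]], on="sample_id", how="left")
    if merged["population"].isna().any():
        orphans = merged.loc[merged["population"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples missing from popmap: {orphans}")
    counts = (
        merged.groupby(["population", "haplogroup"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("population")["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts.sort_values(["population", "haplogroup"]).reset_index(drop=True)


def write_classifications_tsv(results: list[ClassificationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thaplogroup\tmatched_path\tmissing\tconflicts\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.haplogroup}\t{','.join(r.matched_path)}\t"
                f"{','.join(r.missing)}\t{','.join(r.conflicts)}\n"
            )
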