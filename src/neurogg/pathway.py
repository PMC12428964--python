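"""Ganglio-series nomenclature and the biosynthetic graph.

Gangliosides (GGs) are sialylated glycosphingolipids built by stepwise
monosaccharide addition onto ceramide (Cer → GlcCer → LacCer → ...).  The
ganglio-series splits into four branches — 0-, a-, b- and c-series —
according to the number of sialic acids attached to the inner galactose
before the GalNAc step.  The same glycosyltransferases act in parallel on
every branch: B4GALNT1 (GM2/GD2 synthase) converts LacCer→GA2, GM3→GM2 and
GD3→GD2; B3GALT4 and ST3GAL2/3 extend each branch towards the complex
species (GM1a/GD1a, GD1b/GT1b, GA1/GM1b).

This module encodes the species grammar (headgroup plus optional ceramide
anchor such as ``36:1;O2``), series membership, sialic-acid counts, the
directed acyclic biosynthesis graph with enzyme-labelled edges, unique
biosynthetic routes, and inference of enzymatic blocks from
presence/absence patterns (e.g. GM3/GD3-only ⇒ arrest at B4GALNT1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ANCHOR_WHITELIST",
    "ANCHOR_CARBON_WHITELIST",
    "QUANTIFIED_SPECIES",
    "SERIES_MEMBERS",
    "CeramideAnchor",
    "GangliosideSpecies",
    "ParseError",
    "parse_anchor",
    "parse_species",
    "series_of",
    "sialic_count",
    "default_graph",
    "load_graph",
    "save_graph",
    "biosynthetic_route",
    "infer_block",
]

#: Ceramide anchors considered by the assay (total carbons : double bonds ; oxygens).
ANCHOR_WHITELIST: tuple[str, ...] = (
    "32:1;O2", "34:1;O2", "36:1;O2", "38:1;O2", "40:1;O2", "41:1;O2",
    "42:2;O2", "42:1;O2", "43:1;O2", "44:2;O2", "44:1;O2",
)

ANCHOR_CARBON_WHITELIST: frozenset[int] = frozenset({32, 34, 36, 38, 40, 41, 42, 43, 44})

#: The ten headgroups quantified by the assay (anchor-summed panel).
QUANTIFIED_SPECIES: tuple[str, ...] = (
    "GM3", "GM2", "GM1a", "GM1b", "GD1alpha",
    "GD3", "GD2", "GD1a", "GD1b", "GT1b",
)

#: Series membership for every glycan node that carries a series.
SERIES_MEMBERS: dict[str, frozenset[str]] = {
    "0": frozenset({"GA2", "GA1", "GM1b", "GD1alpha", "GD1c"}),
    "a": frozenset({"GM3", "GM2", "GM1a", "GD1a", "GT1a"}),
    "b": frozenset({"GD3", "GD2", "GD1b", "GT1b", "GQ1b"}),
    "c": frozenset({"GT3", "GT2", "GT1c", "GQ1c"}),
}

_PRECURSORS = ("Cer", "GlcCer", "LacCer")

_SIALIC_PREFIX = {"GA": 0, "GM": 1, "GD": 2, "GT": 3, "GQ": 4}


class ParseError(ValueError):
    """Raised when a species or anchor label cannot be parsed."""


@dataclass(frozen=True)
class CeramideAnchor:
    """A ceramide moiety: sphingoid base plus N-acyl chain.

    ``total_carbons`` counts both chains (e.g. d18:1/18:0 → 36),
    ``double_bonds`` the summed unsaturations, ``oxygens`` is fixed at 2
    for the species handled here (sphingosine + amide oxygen).
    """

    total_carbons: int
    double_bonds: int
    oxygens: int = 2

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise ValueError(f"total_carbons must be positive, got {self.total_carbons}")
        if self.double_bonds < 1:
            raise ValueError(f"double_bonds must be >= 1, got {self.double_bonds}")

    @property
    def label(self) -> str:
        """Canonical ``NN:M;O2`` shorthand."""
        return f"{self.total_carbons}:{self.double_bonds};O{self.oxygens}"

    @property
    def whitelisted(self) -> bool:
        return self.label in ANCHOR_WHITELIST


@dataclass(frozen=True)
class GangliosideSpecies:
    """A glycan headgroup with an optional ceramide anchor."""

    glycan: str
    anchor: CeramideAnchor | None = None

    @property
    def label(self) -> str:
        return self.glycan if self.anchor is None else f"{self.glycan} {self.anchor.label}"


_ANCHOR_RE = re.compile(r"^(\d+):(\d+);O(\d+)$")
_ANCHOR_D_RE = re.compile(r"^d(\d+):(\d+)$")


def parse_anchor(text: str) -> CeramideAnchor:
    """Parse ``NN:M;O2`` or the ``dNN:M`` dialect into a :class:`CeramideAnchor`."""
    text = text.strip()
    m = _ANCHOR_RE.match(text)
    if m:
        return CeramideAnchor(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = _ANCHOR_D_RE.match(text)
    if m:
        # the 'd' dialect implies the usual two oxygens
        return CeramideAnchor(int(m.group(1)), int(m.group(2)), 2)
    raise ParseError(f"malformed ceramide anchor: {text!r}")


def _normalize_glycan(name: str) -> str:
    name = name.strip().replace("α", "alpha").replace("Α", "alpha")
    return name


def parse_species(label: str, graph: nx.DiGraph | None = None) -> GangliosideSpecies:
    """Parse ``"GD2"``, ``"GD2 36:1;O2"`` or ``"GD2(d36:1)"`` into a species.

    Unicode alpha is normalised (``GD1α`` → ``GD1alpha``).  The glycan must
    be a node of the biosynthesis graph.
    """
    graph = graph if graph is not None else default_graph()
    label = label.strip()
    anchor: CeramideAnchor | None = None
    m = re.match(r"^(\S+)\((d\d+:\d+)\)$", label)
    if m:
        glycan, anchor = m.group(1), parse_anchor(m.group(2))
    elif " " in label:
        glycan, anchor_text = label.split(None, 1)
        anchor = parse_anchor(anchor_text)
    else:
        glycan = label
    glycan = _normalize_glycan(glycan)
    if glycan not in graph:
        raise ParseError(f"unknown glycan name: {glycan!r}")
    return GangliosideSpecies(glycan, anchor)


def series_of(glycan: str) -> str:
    """Return the series label (``0``/``a``/``b``/``c``) of a glycan headgroup."""
    glycan = _normalize_glycan(glycan)
    for series, members in SERIES_MEMBERS.items():
        if glycan in members:
            return series
    raise ValueError(f"no series defined for glycan {glycan!r}")


def sialic_count(glycan: str) -> int:
    """Number of sialic acid residues implied by the M/D/T/Q prefix (GA → 0)."""
    glycan = _normalize_glycan(glycan)
    if glycan in _PRECURSORS:
        return 0
    prefix = glycan[:2]
    try:
        return _SIALIC_PREFIX[prefix]
    except KeyError:
        raise ValueError(f"unknown glycan prefix in {glycan!r}") from None


# --- biosynthesis graph -----------------------------------------------------

_GRAPH_RESOURCE = "pathway_edges.tsv"
_graph_cache: nx.DiGraph | None = None


def load_graph(path_or_lines: str | Iterable[str]) -> nx.DiGraph:
    """Load a biosynthesis graph from an edge-list TSV.

    Columns: ``precursor``, ``product``, ``enzyme_gene``, ``silent``
    (``silent`` = 1 marks default-inactive branches: the unexpressed
    0-series and the c-series sink).
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    header = lines[0].rstrip("\n").split("\t")
    expected = ["precursor", "product", "enzyme_gene", "silent"]
    if header != expected:
        raise ValueError(f"bad edge-list header {header!r}, expected {expected!r}")
    g = nx.DiGraph()
    for line in lines[1:]:
        if not line.strip():
            continue
        pre, prod, enzyme, silent = line.rstrip("\n").split("\t")
        g.add_edge(pre, prod, enzyme=enzyme, silent=bool(int(silent)))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("biosynthesis graph must be acyclic")
    return g


def save_graph(graph: nx.DiGraph, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("precursor\tproduct\tenzyme_gene\tsilent\n")
        for pre, prod, data in graph.edges(data=True):
            fh.write(f"{pre}\t{prod}\t{data['enzyme']}\t{int(data.get('silent', False))}\n")


def default_graph() -> nx.DiGraph:
    """The shipped ganglio-series graph (shared, read-only)."""
    global _graph_cache
    if _graph_cache is None:
        text = resources.files("neurogg.data").joinpath(_GRAPH_RESOURCE).read_text("utf-8")
        _graph_cache = load_graph(text.splitlines())
        _graph_cache = nx.freeze(_graph_cache)
    return _graph_cache


def biosynthetic_route(glycan: str, graph: nx.DiGraph | None = None) -> list[tuple[str, str]]:
    """Unique route Cer → ... → ``glycan`` as ``(precursor, enzyme_gene)`` steps.

    The glycan graph is a tree rooted at Cer, so the route is unique; an
    unreachable or unknown node raises ``ValueError``.
    """
    graph = graph if graph is not None else default_graph()
    glycan = _normalize_glycan(glycan)
    if glycan not in graph:
        raise ValueError(f"unknown glycan {glycan!r}")
    route: list[tuple[str, str]] = []
    node = glycan
    while node != "Cer":
        preds = list(graph.predecessors(node))
        if not preds:
            raise ValueError(f"{glycan!r} is not reachable from Cer")
        if len(preds) > 1:
            raise ValueError(f"ambiguous route: {node!r} has several precursors")
        pre = preds[0]
        route.append((pre, graph.edges[pre, node]["enzyme"]))
        node = pre
    route.reverse()
    return route


def infer_block(
    abundance_flags: Mapping[str, bool],
    graph: nx.DiGraph | None = None,
    root: str = "LacCer",
) -> set[str]:
    """Infer enzymes whose loss explains a presence/absence pattern.

    An enzyme is returned when (i) at least one of its substrates is
    present and (ii) every flagged species that becomes unreachable from
    ``root`` once the enzyme's edges are deleted is absent — with at least
    one such species, so enzymes feeding only unobserved branches are not
    reported.  GM3/GD3-only input therefore yields ``{"B4GALNT1"}``
    (synthesis arrest at the GM2/GD2 synthase).
    """
    graph = graph if graph is not None else default_graph()
    flags = {_normalize_glycan(k): bool(v) for k, v in abundance_flags.items()}
    if not any(flags.values()):
        raise ValueError("all species absent: no block can be inferred")
    reachable_full = nx.descendants(graph, root) | {root}
    enzymes = {data["enzyme"] for _, _, data in graph.edges(data=True)}
    blocked: set[str] = set()
    for enzyme in enzymes:
        edges = [(u, v) for u, v, d in graph.edges(data=True) if d["enzyme"] == enzyme]
        if not any(flags.get(u, False) for u, _ in edges):
            continue
        pruned = nx.restricted_view(
            graph, nodes=[], edges=edges
        )
        reachable_pruned = nx.descendants(pruned, root) | {root}
        lost = reachable_full - reachable_pruned
        flagged_lost = [n for n in lost if n in flags]
        if flagged_lost and not any(flags[n] for n in flagged_lost):
            blocked.add(enzyme)
    return blocked
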