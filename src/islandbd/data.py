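"""Island community phylogenetic data: types, validation, I/O, timelines.

The unit of data is one island (or archipelago) of known age, colonized from a
mainland pool of ``M`` candidate species.  Each colonist clade is summarized by
its colonization age (the stem age of the island clade, i.e. the divergence
from its mainland sister), the branching ages of its reconstructed island
phylogeny, and an endemicity status.  All times are ages in My before present
(present = 0, island origin = ``island_age``).

Formats: a canonical JSON schema, a DAISIE-style tab-separated colonization
table, and extraction from Newick trees (via dendropy).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "STATUSES",
    "CladeRecord",
    "IslandDataset",
    "TimelineEvent",
    "EventTimeline",
    "MissingSpeciesAssignment",
    "validate_dataset",
    "read_dataset",
    "write_dataset",
    "dataset_from_json",
    "dataset_to_json",
    "event_timeline",
    "extract_island_clades",
    "insert_missing_species",
]

STATUSES = ("endemic_clade", "non_endemic_singleton", "endemic_singleton")


@dataclass(frozen=True)
class CladeRecord:
    """One island colonist clade.

    ``branching_ages`` holds the crown age and subsequent split ages of the
    reconstructed island clade, descending; it is empty for singletons.
    ``mainland_species_id`` identifies the mainland ancestor (1..M).
    """

    name: str
    mainland_species_id: int
    status: str
    colonization_age: float
    branching_ages: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "branching_ages", tuple(sorted(self.branching_ages, reverse=True))
        )

    @property
    def n_species(self) -> int:
        return 1 + len(self.branching_ages)


@dataclass(frozen=True)
class IslandDataset:
    """An island age, a mainland pool size and the colonist clade records."""

    island_age: float
    mainland_pool_M: int
    clades: tuple[CladeRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "clades",
            tuple(sorted(self.clades, key=lambda c: (-c.colonization_age, c.name))),
        )

    @property
    def total_species(self) -> int:
        return sum(c.n_species for c in self.clades)

    @property
    def n_clades(self) -> int:
        return len(self.clades)


@dataclass(frozen=True)
class TimelineEvent:
    age: float
    kind: str  # origin | colonization | branching | present
    clade: str | None
    k_before: int
    k_after: int


@dataclass(frozen=True)
class EventTimeline:
    events: tuple[TimelineEvent, ...]

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class MissingSpeciesAssignment:
    """Placement rule for one unsampled extant species.

    ``insertion_mode="tip_branch"``: graft uniformly along the terminal branch
    of the anchor tip.  ``insertion_mode="within_clade"``: graft uniformly over
    the total branch length of the crown subtree spanned by the anchor tips.
    """

    species: str
    insertion_mode: str
    anchor: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.insertion_mode not in ("tip_branch", "within_clade"):
            raise ValueError(f"unknown insertion_mode {self.insertion_mode!r}")
        anchor = (self.anchor,) if isinstance(self.anchor, str) else tuple(self.anchor)
        object.__setattr__(self, "anchor", anchor)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: IslandDataset) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Never raises; every message names the clade and the rule broken.
    """
    out: list[str] = []
    if not (ds.island_age > 0):
        out.append(f"dataset: island_age must be positive, got {ds.island_age}")
    if not (isinstance(ds.mainland_pool_M, int) and ds.mainland_pool_M >= 1):
        out.append(f"dataset: mainland_pool_M must be a positive integer, got {ds.mainland_pool_M}")
    seen_ids: dict[int, str] = {}
    seen_names: set[str] = set()
    for c in ds.clades:
        if c.name in seen_names:
            out.append(f"clade {c.name}: duplicate clade name")
        seen_names.add(c.name)
        if c.status not in STATUSES:
            out.append(f"clade {c.name}: unknown status {c.status!r}")
        if not (0 < c.colonization_age < ds.island_age):
            out.append(
                f"clade {c.name}: colonization predates island or is non-positive "
                f"(colonization_age={c.colonization_age}, island_age={ds.island_age})"
            )
        ages = c.branching_ages
        for b in ages:
            if not (b > 0):
                out.append(f"clade {c.name}: branching age {b} is not positive")
            if b >= c.colonization_age:
                out.append(
                    f"clade {c.name}: branching precedes colonization "
                    f"(branching age {b} >= colonization age {c.colonization_age})"
                )
        if any(a == b for a, b in zip(ages, ages[1:])):
            out.append(f"clade {c.name}: branching ages not strictly decreasing")
        if c.status == "endemic_clade" and len(ages) < 1:
            out.append(f"clade {c.name}: status endemic_clade requires at least one branching")
        if c.status in ("non_endemic_singleton", "endemic_singleton") and len(ages) > 0:
            out.append(f"clade {c.name}: singleton status but has branching ages")
        if not (1 <= c.mainland_species_id <= ds.mainland_pool_M):
            out.append(
                f"clade {c.name}: mainland_species_id {c.mainland_species_id} "
                f"outside [1, {ds.mainland_pool_M}]"
            )
        if c.mainland_species_id in seen_ids:
            out.append(
                f"clade {c.name}: shares mainland_species_id {c.mainland_species_id} "
                f"with clade {seen_ids[c.mainland_species_id]} (recolonization doublets unsupported)"
            )
        else:
            seen_ids[c.mainland_species_id] = c.name
    return out


class DatasetError(ValueError):
    pass


def _require_valid(ds: IslandDataset) -> None:
    v = validate_dataset(ds)
    if v:
        raise DatasetError("invalid dataset: " + "; ".join(v))


# ---------------------------------------------------------------------------
# JSON / TSV I/O
# ---------------------------------------------------------------------------

def dataset_to_json(ds: IslandDataset) -> str:
    doc = {
        "island_age": ds.island_age,
        "M": ds.mainland_pool_M,
        "clades": [
            {
                "name": c.name,
                "mainland_species_id": c.mainland_species_id,
                "status": c.status,
                "colonization_age": c.colonization_age,
                "branching_ages": list(c.branching_ages),
            }
            for c in ds.clades
        ],
    }
    return json.dumps(doc, indent=2)


def dataset_from_json(text: str) -> IslandDataset:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise DatasetError(f"malformed JSON: {e}") from e
    for key in ("island_age", "M", "clades"):
        if key not in doc:
            raise DatasetError(f"JSON dataset missing required field {key!r}")
    clades = []
    for i, c in enumerate(doc["clades"]):
        for key in ("name", "status", "colonization_age"):
            if key not in c:
                raise DatasetError(f"clade entry {i}: missing field {key!r}")
        clades.append(
            CladeRecord(
                name=str(c["name"]),
                mainland_species_id=int(c.get("mainland_species_id", i + 1)),
                status=str(c["status"]),
                colonization_age=float(c["colonization_age"]),
                branching_ages=tuple(float(b) for b in c.get("branching_ages", [])),
            )
        )
    ds = IslandDataset(
        island_age=float(doc["island_age"]),
        mainland_pool_M=int(doc["M"]),
        clades=tuple(clades),
    )
    _require_valid(ds)
    return ds


def dataset_to_tsv(ds: IslandDataset) -> str:
    """DAISIE-style colonization table.

    Branching_times lists the colonization age first, then the branching ages,
    comma-separated.  Island age and mainland pool size travel in header
    comments so the file round-trips on its own.
    """
    buf = io.StringIO()
    buf.write(f"# island_age={ds.island_age!r}\n")
    buf.write(f"# M={ds.mainland_pool_M}\n")
    buf.write("Clade_name\tStatus\tMissing_species\tBranching_times\tMainland_species_id\n")
    for c in ds.clades:
        times = ",".join(repr(float(t)) for t in (c.colonization_age,) + c.branching_ages)
        buf.write(f"{c.name}\t{c.status}\t0\t{times}\t{c.mainland_species_id}\n")
    return buf.getvalue()


def dataset_from_tsv(text: str) -> IslandDataset:
    island_age = None
    M = None
    clades = []
    lines = text.splitlines()
    header_seen = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("island_age="):
                island_age = float(body.split("=", 1)[1])
            elif body.startswith("M="):
                M = int(body.split("=", 1)[1])
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise DatasetError(f"TSV line {ln}: expected >=4 tab-separated fields")
        name, status, missing, times = parts[:4]
        if int(missing) != 0:
            raise DatasetError(
                f"TSV line {ln}: missing-species counts are unsupported (full sampling assumed)"
            )
        try:
            ages = [float(x) for x in times.split(",") if x != ""]
        except ValueError as e:
            raise DatasetError(f"TSV line {ln}: bad Branching_times field: {e}") from e
        if not ages:
            raise DatasetError(f"TSV line {ln}: empty Branching_times field")
        mid = int(parts[4]) if len(parts) > 4 else len(clades) + 1
        clades.append(
            CladeRecord(
                name=name,
                mainland_species_id=mid,
                status=status,
                colonization_age=ages[0],
                branching_ages=tuple(ages[1:]),
            )
        )
    if island_age is None or M is None:
        raise DatasetError("TSV dataset missing '# island_age=' or '# M=' header line")
    ds = IslandDataset(island_age=island_age, mainland_pool_M=M, clades=tuple(clades))
    _require_valid(ds)
    return ds


def write_dataset(ds: IslandDataset, path, format: str = "json") -> None:
    _require_valid(ds)
    if format == "json":
        text = dataset_to_json(ds)
    elif format == "tsv":
        text = dataset_to_tsv(ds)
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)


def read_dataset(path, format: str | None = None) -> IslandDataset:
    if format is None:
        format = "tsv" if str(path).endswith((".tsv", ".txt")) else "json"
    with open(path) as fh:
        text = fh.read()
    if format == "json":
        return dataset_from_json(text)
    if format == "tsv":
        return dataset_from_tsv(text)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# event timeline
# ---------------------------------------------------------------------------

def event_timeline(ds: IslandDataset) -> EventTimeline:
    """Merge per-clade events into one age-descending timeline.

    Simultaneous ages are broken deterministically: colonization before
    branching, then by clade name, so likelihood evaluation is reproducible.
    """
    _require_valid(ds)
    raw: list[tuple[float, int, str, str]] = []
    for c in ds.clades:
        raw.append((c.colonization_age, 0, c.name, "colonization"))
        for b in c.branching_ages:
            raw.append((b, 1, c.name, "branching"))
    raw.sort(key=lambda e: (-e[0], e[1], e[2]))
    events = [TimelineEvent(ds.island_age, "origin", None, 0, 0)]
    k = 0
    for age, _, name, kind in raw:
        events.append(TimelineEvent(age, kind, name, k, k + 1))
        k += 1
    events.append(TimelineEvent(0.0, "present", None, k, k))
    return EventTimeline(tuple(events))


def dataset_to_newick(ds: IslandDataset) -> tuple[str, set[str]]:
    """Render a dataset as an ultrametric Newick tree with mainland sisters.

    Each island clade becomes a pectinate subtree with the recorded branching
    ages, attached at its stem (colonization) age to a mainland sister tip;
    the stems hang off a mainland backbone reaching the island age.  Returns
    the Newick string and the set of island tip labels, suitable for testing
    :func:`extract_island_clades` round trips.
    """
    _require_valid(ds)

    def _f(x) -> str:
        return repr(float(x))

    def clade_subtree(c: CladeRecord) -> tuple[str, float]:
        tips = [f"{c.name}_sp{i + 1}" for i in range(c.n_species)]
        if c.n_species == 1:
            return tips[0], 0.0
        ages = list(c.branching_ages)

        def sub(j: int) -> tuple[str, float]:
            if j == len(ages) - 1:
                return f"({tips[j]}:{_f(ages[j])},{tips[j + 1]}:{_f(ages[j])})", ages[j]
            inner, h = sub(j + 1)
            return f"({tips[j]}:{_f(ages[j])},{inner}:{_f(ages[j] - h)})", ages[j]

        return sub(0)

    units = []
    for c in ds.clades:  # sorted by colonization age descending
        sub, h = clade_subtree(c)
        a = c.colonization_age
        units.append((f"({sub}:{_f(a - h)},ml_{c.name}:{_f(a)})", a))

    island_tips = {f"{c.name}_sp{i + 1}" for c in ds.clades for i in range(c.n_species)}
    T = ds.island_age
    if not units:
        return f"(ml_a:{_f(T)},ml_b:{_f(T)});", island_tips
    tail = "ml_root"
    tail_age = 0.0
    for sub, a in reversed(units):  # youngest stem first, walking rootward
        node_age = max(a, tail_age) + 0.5 * (T - max(a, tail_age))
        tail = f"({sub}:{_f(node_age - a)},{tail}:{_f(node_age - tail_age)})"
        tail_age = node_age
    newick = f"({tail}:{_f(T - tail_age)},ml_out:{_f(T)});"
    return newick, island_tips

def _node_ages(tree: dendropy.Tree, rel_tol: float) -> dict:
    """Ages (time before the latest tip) of all nodes; checks ultrametricity."""
    tree.calc_node_ages(ultrametricity_precision=False, is_force_max_age=False)
    depths = {}
    for nd in tree.preorder_node_iter():
        d = 0.0 if nd.parent_node is None else depths[nd.parent_node] + (nd.edge.length or 0.0)
        depths[nd] = d
    height = max(depths[lf] for lf in tree.leaf_node_iter())
    tol = rel_tol * height if height > 0 else rel_tol
    for lf in tree.leaf_node_iter():
        if abs(depths[lf] - height) > tol:
            raise ValueError(
                f"tree is not ultrametric within tolerance: tip {lf.taxon.label!r} "
                f"depth {depths[lf]} vs height {height}"
            )
    ages = {}
    for nd, d in depths.items():
        age = height - d
        ages[nd] = 0.0 if abs(age) <= tol else age
    return ages


def extract_island_clades(
    newick: str,
    island_tip_labels: Iterable[str],
    *,
    island_age: float | None = None,
    mainland_pool_M: int = 1000,
    non_endemic_labels: Iterable[str] = (),
    ultrametricity_rel_tol: float = 1e-6,
) -> IslandDataset:
    """Read island clades (stem ages + branching ages) off an ultrametric tree.

    Island tips must form maximal monophyletic groups each with a non-island
    sister; the stem age (the age of the parent node of each maximal island
    clade) is the colonization age, internal node ages within the clade are
    the branching ages.  Singleton island clades get status endemic_singleton
    unless listed in ``non_endemic_labels``.
    """
    island = set(island_tip_labels)
    non_endemic = set(non_endemic_labels)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    ages = _node_ages(tree, ultrametricity_rel_tol)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = island - labels
    if missing:
        raise ValueError(f"island tips not in tree: {sorted(missing)}")

    pure: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            pure[nd] = nd.taxon.label in island
        else:
            pure[nd] = all(pure[ch] for ch in nd.child_nodes())
    if pure[tree.seed_node]:
        raise ValueError("all tips are island tips: no non-island sister to anchor a stem age")

    clades = []
    idx = 0
    for nd in tree.preorder_node_iter():
        if pure[nd] and (nd.parent_node is None or not pure[nd.parent_node]):
            if nd.parent_node is None:
                raise ValueError("island clade spans the root: no stem age available")
            idx += 1
            stem_age = ages[nd.parent_node]
            tips = [lf.taxon.label for lf in nd.leaf_iter()]
            internal_ages = tuple(
                sorted((ages[x] for x in nd.preorder_iter() if not x.is_leaf()), reverse=True)
            )
            if len(tips) == 1:
                status = (
                    "non_endemic_singleton" if tips[0] in non_endemic else "endemic_singleton"
                )
            else:
                status = "endemic_clade"
            clades.append(
                CladeRecord(
                    name=f"clade_{idx}",
                    mainland_species_id=idx,
                    status=status,
                    colonization_age=stem_age,
                    branching_ages=internal_ages,
                )
            )
    if island_age is None:
        island_age = ages[tree.seed_node] * (1.0 + 1e-9) + 1e-12
    ds = IslandDataset(island_age=island_age, mainland_pool_M=mainland_pool_M, clades=tuple(clades))
    return ds


def _mrca(nodes) -> "dendropy.Node":
    """Most recent common ancestor by ancestor-set intersection (no side effects)."""
    paths = []
    for nd in nodes:
        path = []
        x = nd
        while x is not None:
            path.append(x)
            x = x.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        first = paths[0][depth]
        if all(p[depth] is first for p in paths):
            mrca = first
        else:
            break
    return mrca


def _subtree_edges(node) -> list:
    """Edges of the crown subtree rooted at ``node`` (excluding its stem edge)."""
    edges = []
    for nd in node.preorder_iter():
        if nd is node:
            continue
        edges.append(nd)
    return edges


def insert_missing_species(
    newick: str,
    assignments: Sequence[MissingSpeciesAssignment],
    n_replicates: int,
    seed: int,
    *,
    ultrametricity_rel_tol: float = 1e-6,
) -> list[str]:
    """Graft unsampled extant species onto random positions, ``n_replicates`` times.

    Each replicate re-reads the input tree, adds one age-0 tip per assignment
    and returns the Newick string.  ``tip_branch`` assignments attach uniformly
    along the anchor tip's terminal branch; ``within_clade`` assignments attach
    uniformly over the summed branch length of the anchor clade's crown
    subtree.  Output trees remain ultrametric.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        for a in assignments:
            ages = _node_ages(tree, ultrametricity_rel_tol)
            label_map = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
            for lbl in a.anchor:
                if lbl not in label_map:
                    raise ValueError(f"anchor tip {lbl!r} not found for species {a.species!r}")
            if a.insertion_mode == "tip_branch":
                tip = label_map[a.anchor[0]]
                lo, hi = ages[tip], ages[tip.parent_node]
                attach_node, attach_age = tip, float(rng.uniform(lo, hi))
            else:
                anchors = [label_map[lbl] for lbl in a.anchor]
                mrca = anchors[0] if len(anchors) == 1 else _mrca(anchors)
                cand = _subtree_edges(mrca)
                if not cand:
                    raise ValueError(
                        f"anchor clade for species {a.species!r} has an empty crown subtree"
                    )
                lens = np.array([nd.edge.length or 0.0 for nd in cand])
                total = lens.sum()
                if total <= 0:
                    raise ValueError(f"anchor clade for {a.species!r} has zero branch length")
                j = int(rng.choice(len(cand), p=lens / total))
                attach_node = cand[j]
                attach_age = float(
                    rng.uniform(ages[attach_node], ages[attach_node.parent_node])
                )
            _graft_tip(tree, attach_node, attach_age, a.species, ages)
        out.append(
            tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )
    return out


def _graft_tip(tree, node, attach_age: float, label: str, ages: dict) -> None:
    """Split ``node``'s stem edge at ``attach_age`` and hang a new age-0 tip."""
    parent = node.parent_node
    new_inner = dendropy.Node()
    parent.remove_child(node)
    parent.add_child(new_inner)
    new_inner.edge.length = ages[parent] - attach_age
    new_inner.add_child(node)
    node.edge.length = attach_age - ages[node]
    tip = dendropy.Node()
    tip.taxon = tree.taxon_namespace.new_taxon(label)
    new_inner.add_child(tip)
    tip.edge.length = attach_age
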