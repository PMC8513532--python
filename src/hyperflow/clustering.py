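"""Activity-driven source clustering and region-group construction.

Source vertices are clustered on a 3-vector of features — grand-averaged
beta/low-gamma normalized power in (TeamFlow, TeamOnly, FlowOnly) — with
agglomerative complete-linkage clustering on Euclidean distance.  Clusters
fall into three families by their mean feature pattern:

* ``flow``: power highest in TeamOnly (suppressed whenever flow is present);
* ``team``: power lowest in FlowOnly (raised whenever a partner is present);
* ``teamflow``: power highest in TeamFlow.

ROIs are subdivided where at least two families each hold a sufficient
fraction of the ROI's vertices, and the 14 region groups (7 per hemisphere)
are assembled by putting every significantly condition-modulated ROI into
the marker group (RG7) and the rest into their anatomical super-region's
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from hyperflow.config import CONDITIONS

FAMILIES = ("flow", "team", "teamflow")

#: Anatomical super-region labels for RG1..RG6; RG7 is the significance-
#: defined marker group (middle temporal cortex in the real atlas).
SUPER_REGIONS = ("PFC", "ACC", "IFC", "STC", "CPC", "OC")
MARKER_LABEL = "MTC"


@dataclass
class ClusterLabeling:
    """Vertex cluster assignment with per-cluster family classification."""

    labels: np.ndarray  # vertex -> cluster id in 1..k
    k: int
    cluster_means: np.ndarray  # (k, 3)
    families: list[str | None]  # per cluster; None = unresolved tie

    def family_of_vertex(self) -> np.ndarray:
        return np.array([self.families[l - 1] for l in self.labels], dtype=object)


@dataclass
class RegionGroup:
    name: str  # e.g. "L-RG7"
    hemisphere: str
    label: str  # anatomical label (PFC..OC, MTC)
    members: list[str] = field(default_factory=list)  # ROI/subdivision ids
    family_composition: dict[str, float] = field(default_factory=dict)


@dataclass
class RegionGroupSet:
    groups: list[RegionGroup]

    def __post_init__(self) -> None:
        if len(self.groups) != 14:
            raise ValueError(f"expected 14 region groups, got {len(self.groups)}")

    def by_name(self, name: str) -> RegionGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def member_map(self) -> dict[str, str]:
        """subdivision id -> group name; raises if groups overlap."""
        out: dict[str, str] = {}
        for g in self.groups:
            for m in g.members:
                if m in out:
                    raise ValueError(f"member {m} in two groups")
                out[m] = g.name
        return out


def cluster_vertices(features: np.ndarray, k: int) -> ClusterLabeling:
    """Complete-linkage agglomerative clustering on Euclidean distance.

    ``features`` is (n_vertices, 3).  Deterministic for a given feature set;
    cluster ids are relabelled 1..k by order of first appearance so the
    labelling does not depend on vertex input order beyond the geometry.
    """
    features = np.asarray(features, dtype=float)
    n = len(features)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in 1..{n}")
    if features.ndim != 2 or features.shape[1] != 3:
        raise ValueError("features must be (n_vertices, 3)")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        z = linkage(features, method="complete", metric="euclidean")
        labels = fcluster(z, t=k, criterion="maxclust")
    # canonical relabelling by first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[l] for l in labels])
    k_eff = labels.max()
    means = np.stack([features[labels == c].mean(axis=0) for c in range(1, k_eff + 1)])
    families = [classify_family(m, strict=False) for m in means]
    return ClusterLabeling(labels=labels, k=k_eff, cluster_means=means, families=families)


def classify_family(mean_features: np.ndarray, strict: bool = True) -> str | None:
    """Family of a cluster from its mean (TeamFlow, TeamOnly, FlowOnly) power.

    Each family has a defining margin: ``flow`` is "TeamOnly high alone"
    (power suppressed whenever flow is present), ``teamflow`` is "TeamFlow
    high alone", ``team`` is "FlowOnly low alone" (power raised whenever a
    partner is present).  The family whose margin is largest (and positive)
    wins; margin ties fall to the precedence teamflow > flow > team, and a
    pattern with no positive margin (exact three-way tie) is unresolved:
    ``None`` is returned, or an error raised when ``strict``.
    """
    tf, to, fo = (float(v) for v in mean_features)
    if not all(np.isfinite([tf, to, fo])):
        raise ValueError("cluster mean features must be finite")
    margins = {
        "teamflow": tf - max(to, fo),
        "flow": to - max(tf, fo),
        "team": min(tf, to) - fo,
    }
    best = max(margins.values())
    family: str | None = None
    if best > 0:
        for name in ("teamflow", "flow", "team"):  # precedence on ties
            if margins[name] == best:
                family = name
                break
    if family is None and strict:
        raise ValueError(f"tied feature pattern {mean_features}: family unresolved")
    return family


def subdivide_roi(
    vertex_families: np.ndarray,
    roi_id: str = "roi",
    threshold: float = 0.20,
) -> list[tuple[str, str, np.ndarray]]:
    """Split an ROI into family subdivisions by cumulative composition.

    Families holding at least ``threshold`` of the ROI's vertices each form
    a subdivision ``(subdivision_id, family, vertex_index_array)``; vertices
    of below-threshold families are absorbed into the largest subdivision so
    the subdivisions always partition the ROI.  An ROI with a single
    qualifying family stays whole.
    """
    fams = np.asarray(vertex_families, dtype=object)
    if any(f is None for f in fams):
        raise ValueError(f"{roi_id}: unlabeled vertices cannot be subdivided")
    n = len(fams)
    fractions = {f: float(np.sum(fams == f)) / n for f in FAMILIES if np.any(fams == f)}
    qualifying = [f for f in FAMILIES if fractions.get(f, 0.0) >= threshold]
    if len(qualifying) <= 1:
        return [(roi_id, max(fractions, key=fractions.get), np.arange(n))]
    main = max(qualifying, key=lambda f: fractions[f])
    parts = []
    leftover = np.array([f not in qualifying for f in fams], dtype=bool)
    for f in qualifying:
        idx = np.flatnonzero((fams == f) | (leftover if f == main else False))
        parts.append((f"{roi_id}.{f}", f, idx))
    return parts


def build_region_groups(
    roi_significant: dict[str, bool],
    subdivisions: dict[str, list[tuple[str, str, np.ndarray]]],
    anatomy: dict[str, tuple[str, str]],
) -> RegionGroupSet:
    """Assemble the 14 region groups from flags, subdivisions and anatomy.

    ``anatomy`` maps ROI id -> (hemisphere in {"L", "R"}, super-region in
    ``SUPER_REGIONS``).  Significant ROIs go whole into their hemisphere's
    RG7 regardless of composition; other ROIs' subdivisions go to the group
    of their super-region.
    """
    groups = {
        (h, i): RegionGroup(
            name=f"{h}-RG{i + 1}",
            hemisphere=h,
            label=(SUPER_REGIONS[i] if i < 6 else MARKER_LABEL),
        )
        for h in ("L", "R")
        for i in range(7)
    }
    fam_counts: dict[str, dict[str, int]] = {g.name: {} for g in groups.values()}
    for roi, flags in roi_significant.items():
        if roi not in anatomy:
            raise KeyError(f"ROI {roi} missing from anatomical map")
        hemi, super_region = anatomy[roi]
        parts = subdivisions.get(roi, [(roi, None, np.array([]))])
        if flags:
            target = groups[(hemi, 6)]
            target.members.append(roi)
            for _, fam, idx in parts:
                if fam is not None:
                    fam_counts[target.name][fam] = (
                        fam_counts[target.name].get(fam, 0) + len(idx)
                    )
        else:
            gi = SUPER_REGIONS.index(super_region)
            target = groups[(hemi, gi)]
            for sub_id, fam, idx in parts:
                target.members.append(sub_id)
                if fam is not None:
                    fam_counts[target.name][fam] = (
                        fam_counts[target.name].get(fam, 0) + len(idx)
                    )
    for g in groups.values():
        total = sum(fam_counts[g.name].values())
        if total:
            g.family_composition = {
                f: 100.0 * c / total for f, c in fam_counts[g.name].items()
            }
    if all(roi_significant.values()) and roi_significant:
        warnings.warn("all ROIs significant: RG1-RG6 are empty")
    ordered = [groups[(h, i)] for h in ("L", "R") for i in range(7)]
    return RegionGroupSet(groups=ordered)


def aggregate_rg_series(
    unit_series: dict[str, np.ndarray], groups: RegionGroupSet
) -> tuple[np.ndarray, list[str]]:
    """Per-group unweighted mean series -> (14 x time array, group names).

    Empty groups yield all-NaN rows (downstream stages skip them).
    """
    lengths = {s.shape[-1] for s in unit_series.values()}
    if len(lengths) > 1:
        raise ValueError("member series have differing lengths")
    n = lengths.pop()
    out = np.full((14, n), np.nan)
    names = []
    for gi, g in enumerate(groups.groups):
        names.append(g.name)
        members = [m for m in g.members if m in unit_series]
        if len(members) != len(g.members):
            missing = set(g.members) - set(members)
            raise KeyError(f"group {g.name} missing member series: {missing}")
        if members:
            out[gi] = np.mean([unit_series[m] for m in members], axis=0)
    return out, names
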