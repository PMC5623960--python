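"""Grouping of co-eluting features into per-molecule clusters.

Features whose FWQM retention windows overlap are candidate pairs; a pair
is admitted when the Pearson correlation of their intensity traces over
the shared scans exceeds the threshold (strictly), and groups are the
single-linkage closure of admitted pairs. A deterministic role annotator
replaces the manual curation step: within a group, m/z differences that
match adduct-component differences or the acetoxy-loss fragment are
labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import chem
from .signal import PeakFeature

logger = logging.getLogger(__name__)

MIN_COMMON_SCANS = 4
CORRELATION_THRESHOLD = 0.9

#: monoisotopic mass of the acetoxy-loss neutral fragment (C2H4O2)
ACETOXY_LOSS = chem.monoisotopic_mass("C2H4O2")  # 60.02113

#: pairwise adduct-component mass differences, singly charged
_ADDUCT_DELTAS = {
    ("[M+H]+", "[M+NH4]+"): chem.ADDUCT_COMPONENT_MASS["NH4"] - chem.ADDUCT_COMPONENT_MASS["H"],
    ("[M+H]+", "[M+Na]+"): chem.ADDUCT_COMPONENT_MASS["Na"] - chem.ADDUCT_COMPONENT_MASS["H"],
    ("[M+H]+", "[M+K]+"): chem.ADDUCT_COMPONENT_MASS["K"] - chem.ADDUCT_COMPONENT_MASS["H"],
    ("[M+NH4]+", "[M+Na]+"): chem.ADDUCT_COMPONENT_MASS["Na"] - chem.ADDUCT_COMPONENT_MASS["NH4"],
    ("[M+NH4]+", "[M+K]+"): chem.ADDUCT_COMPONENT_MASS["K"] - chem.ADDUCT_COMPONENT_MASS["NH4"],
    ("[M+Na]+", "[M+K]+"): chem.ADDUCT_COMPONENT_MASS["K"] - chem.ADDUCT_COMPONENT_MASS["Na"],
}


@dataclass
class FeatureGroup:
    """Features attributed to one molecule (adducts, fragments, artifacts)."""

    member_ids: list[int]
    correlations: dict[tuple[int, int], float] = field(default_factory=dict)
    roles: dict[int, str] = field(default_factory=dict)
    representative_id: int = -1
    consensus_rt: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_ids)


def find_candidates(features: list[PeakFeature]) -> list[tuple[int, int]]:
    """Pairs whose closed FWQM retention intervals intersect."""
    pairs = []
    for f, g in combinations(features, 2):
        lo = max(f.fwqm_bounds[0], g.fwqm_bounds[0])
        hi = min(f.fwqm_bounds[1], g.fwqm_bounds[1])
        if lo <= hi:
            pairs.append((f.feature_id, g.feature_id))
    return pairs


def trace_correlation(f: PeakFeature, g: PeakFeature) -> float | None:
    """Pearson correlation over the shared scans of two FWQM traces.

    Returns None when fewer than MIN_COMMON_SCANS scans are shared.
    Traces are matched on their scan time stamps (tolerance: half the
    local scan spacing).
    """
    tf, tg = f.trace_times, g.trace_times
    if tf.size < 2 or tg.size < 2:
        return None
    dt = min(np.min(np.diff(tf)), np.min(np.diff(tg)))
    common_f, common_g = [], []
    j = 0
    for i, t in enumerate(tf):
        while j < tg.size and tg[j] < t - dt / 2:
            j += 1
        if j < tg.size and abs(tg[j] - t) <= dt / 2:
            common_f.append(f.trace_intensities[i])
            common_g.append(g.trace_intensities[j])
    if len(common_f) < MIN_COMMON_SCANS:
        return None
    a = np.asarray(common_f)
    b = np.asarray(common_g)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def group_by_correlation(
    features: list[PeakFeature],
    candidates: list[tuple[int, int]] | None = None,
    threshold: float = CORRELATION_THRESHOLD,
) -> list[FeatureGroup]:
    """Merge candidate pairs with correlation strictly above the threshold.

    Groups are connected components (single linkage) over admitted pairs;
    unpaired features remain singleton groups.
    """
    by_id = {f.feature_id: f for f in features}
    if candidates is None:
        candidates = find_candidates(features)

    parent = {fid: fid for fid in by_id}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    admitted: dict[tuple[int, int], float] = {}
    for i, j in candidates:
        r = trace_correlation(by_id[i], by_id[j])
        if r is None:
            logger.debug("pair (%d,%d) rejected: <%d common scans", i, j, MIN_COMMON_SCANS)
            continue
        if r > threshold:  # strictly above
            admitted[(i, j)] = r
            parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for fid in by_id:
        clusters.setdefault(find(fid), []).append(fid)

    groups = []
    for members in clusters.values():
        members.sort()
        rep = max(members, key=lambda fid: float(by_id[fid].trace_intensities.sum()))
        rt = float(np.mean([by_id[m].rt_apex for m in members]))
        corr = {
            (i, j): r for (i, j), r in admitted.items() if i in members and j in members
        }
        groups.append(
            FeatureGroup(
                member_ids=members,
                correlations=corr,
                representative_id=rep,
                consensus_rt=rt,
            )
        )
    groups.sort(key=lambda g: g.consensus_rt)
    return groups


def curate_group(
    group: FeatureGroup,
    features: list[PeakFeature],
    mass_tol: float = 0.01,
) -> FeatureGroup:
    """Annotate member roles from m/z differences.

    Pairs matching an adduct-component mass difference get adduct labels;
    a difference matching the acetoxy neutral loss marks a fragment pair.
    Singleton groups get the role "unassigned"; members explained by
    nothing are "unknown-related".
    """
    by_id = {f.feature_id: f for f in features}
    members = group.member_ids
    if len(members) == 1:
        group.roles[members[0]] = "unassigned"
        return group
    roles = {m: "unknown-related" for m in members}
    for i, j in combinations(sorted(members, key=lambda m: by_id[m].mean_mz), 2):
        delta = by_id[j].mean_mz - by_id[i].mean_mz
        for (low_label, high_label), d in _ADDUCT_DELTAS.items():
            if abs(delta - d) <= mass_tol:
                if roles[i] == "unknown-related":
                    roles[i] = low_label
                if roles[j] == "unknown-related":
                    roles[j] = high_label
        if abs(delta - ACETOXY_LOSS) <= mass_tol:
            roles[i] = "acetoxy-loss fragment"
            if roles[j] == "unknown-related":
                roles[j] = "parent of acetoxy loss"
    group.roles.update(roles)
    return group


def has_acetoxy_loss_pair(
    group: FeatureGroup, features: list[PeakFeature], mass_tol: float = 0.01
) -> bool:
    by_id = {f.feature_id: f for f in features}
    for i, j in combinations(group.member_ids, 2):
        if abs(abs(by_id[j].mean_mz - by_id[i].mean_mz) - ACETOXY_LOSS) <= mass_tol:
            return True
    return False
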