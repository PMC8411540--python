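"""Transmission inference: semi-clonal groups, recombination masking,
clonal groups, and metadata-level classification of transmission events.

Pipeline: whole-cohort SNP distances -> semi-clonal groups (single-linkage
at d < 2500, SNPs re-called on each group's own core) -> per-strain
recombination masking (windowed Poisson outlier scan against the group
consensus, a transparent stand-in for a branch-wise recombination model;
external masks can be substituted) -> clonal groups (post-masking d < 10)
-> transmission events classified by the most specific metadata stratum
shared by all members.  Both thresholds are strict "less than".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .coresnp import AlignedGenomeSet, DistanceMatrix, SnpMatrix, call_core_snps
from .errors import FormatError, ParameterError
from .popstruct import single_linkage_clusters

log = logging.getLogger("strainpop")

SCG_THRESHOLD = 2500
CG_THRESHOLD = 10

#: metadata strata from most to least specific; the classifier reports the
#: most specific one shared by every member of a clonal group
STRATA = [
    ("sample_id", "intra-host"),
    ("family_id", "intra-family"),
    ("community_id", "intra-community"),
    ("city", "intra-city"),
    ("province", "intra-province"),
    ("country", "inter-province"),
]
INTER_COUNTRY = "inter-country"


@dataclass
class SemiClonalGroup:
    """Single-linkage cluster at the SCG threshold with its own re-called core."""

    group_id: str
    members: list[str]
    snps: SnpMatrix

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ParameterError("a semi-clonal group needs >= 2 members")


@dataclass
class MaskedScg:
    """An SCG with per-strain recombination masks applied."""

    scg: SemiClonalGroup
    #: strain -> list of 1-based inclusive masked (start, end) bp intervals
    masked_intervals: dict[str, list[tuple[int, int]]]
    #: strain -> boolean mask over the SCG's SNP columns
    site_masks: dict[str, np.ndarray]

    def distances(self) -> DistanceMatrix:
        """Post-masking pairwise distances: a pair's distance excludes sites
        masked in either member (masking never increases any distance)."""
        snps = self.scg.snps
        n = snps.n_strains
        al = snps.alleles
        masks = np.vstack([self.site_masks[s] for s in snps.strain_ids])
        d = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                ok = (al[i] >= 0) & (al[j] >= 0) & ~masks[i] & ~masks[j]
                d[i, j] = d[j, i] = int(np.sum(al[i][ok] != al[j][ok]))
        return DistanceMatrix(list(snps.strain_ids), d)


@dataclass
class ClonalGroup:
    group_id: str
    members: list[str]
    max_pairwise: int
    scg_id: str


@dataclass
class TransmissionEvent:
    clonal_group: str
    level: str
    cross_host_species: bool
    #: False when all members come from one host (single-colonization evidence)
    is_transmission: bool
    members: list[str] = field(default_factory=list)


def find_scgs(
    d: DistanceMatrix,
    genomes: AlignedGenomeSet,
    threshold: int = SCG_THRESHOLD,
    core_fraction: float = 1.0,
) -> list[SemiClonalGroup]:
    """Semi-clonal groups: single-linkage components of {d < threshold} with
    >= 2 members; SNPs are re-called on each group's own core genome."""
    out = []
    for members in single_linkage_clusters(d, threshold):
        if len(members) < 2:
            continue
        snps = call_core_snps(genomes.subset(members), core_fraction=core_fraction)
        out.append(SemiClonalGroup(f"SCG{len(out) + 1}", members, snps))
    return out


def _consensus(snps: SnpMatrix) -> np.ndarray:
    """Site-wise majority allele over the group (ties -> reference allele)."""
    ones = (snps.alleles == 1).sum(axis=0)
    zeros = (snps.alleles == 0).sum(axis=0)
    return (ones > zeros).astype(np.int8)


def _flagged_windows(diff_pos: np.ndarray, window_bp: int, thr: float) -> list[tuple[int, int]]:
    """1-based inclusive intervals of windows (anchored at each difference,
    both directions) whose difference count exceeds ``thr``."""
    flagged = []
    m = diff_pos.size
    for i in range(m):
        p = int(diff_pos[i])
        hi = int(np.searchsorted(diff_pos, p + window_bp, side="left"))
        if hi - i > thr:
            flagged.append((p, p + window_bp - 1))
        lo = int(np.searchsorted(diff_pos, p - window_bp, side="right"))
        if i + 1 - lo > thr:
            flagged.append((p - window_bp + 1, p))
    return flagged


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _dense_runs(start: int, end: int, diff_pos: np.ndarray,
                min_gap: int = 50) -> list[tuple[int, int]]:
    """Shrink a flagged interval to the spans of its runs of differences.

    Every difference caught in a flagged window is masked, but the masked
    *intervals* are the spans of runs split at gaps larger than
    max(5 x median in-interval gap, ``min_gap``).  Isolated background
    differences in the window's reach thus become point masks instead of
    extending the mask by up to a window length beyond a dense tract.
    """
    inside = diff_pos[(diff_pos >= start) & (diff_pos <= end)]
    if inside.size == 0:
        return []
    if inside.size == 1:
        return [(int(inside[0]), int(inside[0]))]
    gaps = np.diff(inside)
    cutoff = max(5.0 * float(np.median(gaps)), float(min_gap))
    breaks = np.flatnonzero(gaps > cutoff)
    return [(int(r[0]), int(r[-1])) for r in np.split(inside, breaks + 1)]


def mask_recombination(
    scg: SemiClonalGroup,
    window_bp: int = 1000,
    tail_p: float = 1e-4,
    external_masks: dict[str, list[tuple[int, int]]] | None = None,
) -> MaskedScg:
    """Mask putative recombination imports per strain.

    Each strain is compared with the SCG consensus; sliding windows
    (anchored at every difference, both directions) whose difference count
    exceeds the Poisson(strain-wide rate x window_bp) upper tail at
    ``tail_p`` are flagged, merged, and trimmed to their dense run of
    differences.  Masked sites are removed from the group matrix for that
    strain's pairs.  ``external_masks`` (e.g. from a dedicated recombination
    detector) replace the scan for the strains they cover.
    """
    snps = scg.snps
    if snps.genome_length <= 0:
        raise FormatError("SCG SnpMatrix lacks genome_length")
    cons = _consensus(snps)
    masked_intervals: dict[str, list[tuple[int, int]]] = {}
    site_masks: dict[str, np.ndarray] = {}
    for i, sid in enumerate(snps.strain_ids):
        if external_masks is not None and sid in external_masks:
            intervals = _merge_intervals(list(external_masks[sid]))
        else:
            row = snps.alleles[i]
            diff = (row >= 0) & (row != cons)
            diff_pos = snps.positions[diff]
            lam = diff_pos.size / snps.genome_length * window_bp
            thr = float(poisson.isf(tail_p, lam)) if lam > 0 else np.inf
            flagged = _flagged_windows(diff_pos, window_bp, thr)
            intervals = []
            for s, e in _merge_intervals(flagged):
                intervals.extend(_dense_runs(s, e, diff_pos))
            intervals = _merge_intervals(intervals)
        masked_intervals[sid] = intervals
        mask = np.zeros(snps.n_sites, dtype=bool)
        for s, e in intervals:
            mask |= (snps.positions >= s) & (snps.positions <= e)
        site_masks[sid] = mask
    return MaskedScg(scg, masked_intervals, site_masks)


def find_cgs(masked: MaskedScg, threshold: int = CG_THRESHOLD) -> list[ClonalGroup]:
    """Clonal groups: single-linkage components of post-masking {d < threshold}
    (strict less-than) with >= 2 members."""
    d = masked.distances()
    out = []
    for members in single_linkage_clusters(d, threshold):
        if len(members) < 2:
            continue
        sub = d.subset(members)
        out.append(ClonalGroup(
            f"{masked.scg.group_id}-CG{len(out) + 1}", members,
            int(sub.values.max()), masked.scg.group_id))
    return out


def classify_transmission(cg: ClonalGroup, meta: pd.DataFrame) -> TransmissionEvent:
    """Classify a clonal group by the most specific shared metadata stratum.

    A group confined to one sample/host is single-colonization evidence, not
    transmission; ``cross_host_species`` is set when members span species.
    """
    missing = [s for s in cg.members if s not in meta.index]
    if missing:
        raise FormatError(f"strain {missing[0]!r} missing from metadata")
    sub = meta.loc[cg.members]
    species = sub["host_species"].dropna().unique() if "host_species" in sub else []
    cross_species = len(species) > 1

    level = INTER_COUNTRY
    for col, name in STRATA:
        vals = sub[col] if col in sub.columns else pd.Series(dtype=object)
        if len(vals) == len(cg.members) and vals.notna().all() and vals.nunique() == 1:
            level = name
            break
    is_transmission = level != "intra-host"
    return TransmissionEvent(cg.group_id, level, cross_species,
                             is_transmission, list(cg.members))


def transmission_table(events: list[TransmissionEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "clonal_group": e.clonal_group, "level": e.level,
        "cross_host_species": e.cross_host_species,
        "is_transmission": e.is_transmission,
        "n_members": len(e.members), "members": ",".join(e.members),
    } for e in events])


def intra_host_summary(masked_groups: list[MaskedScg], meta: pd.DataFrame) -> dict:
    """Median post-masking pairwise distance among same-host isolate pairs."""
    dists = []
    hosts = set()
    for masked in masked_groups:
        d = masked.distances()
        sub = meta.loc[[s for s in d.ids if s in meta.index]]
        for host, grp in sub.groupby("sample_id"):
            ids = list(grp.index)
            if len(ids) < 2:
                continue
            hosts.add(host)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    dists.append(d.loc(ids[i], ids[j]))
    return {
        "n_hosts": len(hosts),
        "n_pairs": len(dists),
        "median": float(np.median(dists)) if dists else np.nan,
    }


def mask_performance(
    masked: MaskedScg, truth_intervals: dict[str, list[tuple[int, int]]]
) -> pd.DataFrame:
    """Per-strain masking sensitivity and false-positive rate in bases.

    ``truth_intervals`` are 0-based half-open planted tracts; sensitivity is
    the fraction of tract bases masked, FPR the fraction of non-tract bases
    masked.
    """
    L = masked.scg.snps.genome_length
    rows = []
    for sid in masked.scg.snps.strain_ids:
        truth = np.zeros(L, dtype=bool)
        for s0, e0 in truth_intervals.get(sid, []):
            truth[s0:e0] = True
        called = np.zeros(L, dtype=bool)
        for s1, e1 in masked.masked_intervals.get(sid, []):
            called[s1 - 1:e1] = True
        tract = int(truth.sum())
        sens = float((called & truth).sum() / tract) if tract else np.nan
        fpr = float((called & ~truth).sum() / (L - tract)) if L > tract else np.nan
        rows.append({"strain": sid, "tract_bp": tract,
                     "sensitivity": sens, "fpr": fpr})
    return pd.DataFrame(rows)
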