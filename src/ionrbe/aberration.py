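"""Chromosome fragments, end rejoining, and lethal-aberration scoring.

Every critical lesion cuts its chromosome into two independent fragments and
creates two free ends at the lesion position.  Free ends rejoin pairwise
under a step function of their initial distance: only ends closer than the
rejoining threshold may join, and each end independently remains un-rejoined
with probability f.  The rearranged elements assembled from fragments and
junctions are scored for dicentrics, centric rings, and large (metaphase
visible) deletions; any of these is lethal to the clonogenic cell.

The module exposes both an object API (Fragment / AberrationTally) mirroring
the model's conceptual steps, and flat-array internals shared with the
survival simulator so the two paths cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, IonRbeError
from .damage import CriticalLesion
from .karyo import TerritoryConfiguration

__all__ = [
    "Fragment",
    "RejoiningParameters",
    "AberrationTally",
    "fragment",
    "rejoin",
    "assemble_and_score",
    "cell_fate",
    "DEFAULT_VISIBILITY_MBP",
    "DEFAULT_F",
]

# "large" deletion = visible when chromatin is condensed; 3 Mbp is the
# conventional Giemsa-band visibility scale
DEFAULT_VISIBILITY_MBP = 3.0
# default per-end un-rejoining probability; chosen (together with the
# calibrated photon CL yield) so the simulated photon response carries the
# low alpha/beta ratio characteristic of a late-responding/radioresistant
# tissue rather than a fibroblast-like high ratio
DEFAULT_F = 0.022


@dataclass(frozen=True)
class RejoiningParameters:
    """Step-function rejoining: threshold distance and un-rejoining probability.

    threshold_um=None means "derive from the territory configuration" (mean
    distance between adjacent territory centres); resolved by callers.
    """

    threshold_um: Optional[float] = None
    f: float = DEFAULT_F

    def __post_init__(self) -> None:
        if self.threshold_um is not None and self.threshold_um <= 0:
            raise ConfigurationError("rejoining threshold must be positive")
        if not (0 <= self.f <= 1):
            raise ConfigurationError("f must be a probability")


@dataclass(frozen=True)
class Fragment:
    """A contiguous chromosome piece delimited by CLs and/or telomeres.

    ``end_ids`` / ``end_positions`` describe the CL-induced free ends
    (telomeric boundaries carry no free end).  End ids are unique within the
    fragment list returned by :func:`fragment`.
    """

    copy: int
    lo_mbp: float
    hi_mbp: float
    centric: bool
    end_ids: tuple[int, ...] = ()
    end_positions: tuple[tuple[float, float, float], ...] = ()

    @property
    def length_mbp(self) -> float:
        return self.hi_mbp - self.lo_mbp


@dataclass
class AberrationTally:
    dicentrics: int = 0
    centric_rings: int = 0
    large_deletions: int = 0

    @property
    def lethal(self) -> bool:
        return (self.dicentrics + self.centric_rings + self.large_deletions) >= 1


def cell_fate(tally: AberrationTally) -> str:
    """'survives' iff the cell carries no lethal aberration."""
    return "dies" if tally.lethal else "survives"


# ---------------------------------------------------------------------------
# array internals (shared with the survival simulator)
# ---------------------------------------------------------------------------

def _fragment_arrays(
    cl_copy: np.ndarray,
    cl_genomic: np.ndarray,
    cl_pos: np.ndarray,
    copy_length: np.ndarray,
    copy_centromere: np.ndarray,
    all_copies: bool = False,
):
    """Split chromosomes at sorted CL positions.

    Returns (frag_copy, frag_lo, frag_hi, frag_centric, end_frag, end_pos)
    where end 2j and 2j+1 are the two free ends created by the j-th CL in
    (copy, genomic) sort order: 2j belongs to the fragment on the p side,
    2j+1 to the fragment on the q side.  When ``all_copies`` is true,
    unbroken chromosome copies are included as endless fragments.
    """
    k = len(cl_copy)
    order = np.lexsort((cl_genomic, cl_copy))
    sc = cl_copy[order]
    sg = cl_genomic[order]
    sp = cl_pos[order]

    frag_copy, frag_lo, frag_hi = [], [], []
    end_frag = np.empty(2 * k, dtype=np.int64)
    end_pos = np.empty((2 * k, 3))

    hit_copies = []
    start = 0
    while start < k:
        stop = start
        c = sc[start]
        while stop < k and sc[stop] == c:
            stop += 1
        hit_copies.append(int(c))
        m = stop - start
        base = len(frag_copy)
        cuts = sg[start:stop]
        lo = np.concatenate([[0.0], cuts])
        hi = np.concatenate([cuts, [copy_length[c]]])
        frag_copy.extend([int(c)] * (m + 1))
        frag_lo.extend(lo.tolist())
        frag_hi.extend(hi.tolist())
        for j in range(m):
            e = 2 * (start + j)
            end_frag[e] = base + j        # p-side fragment
            end_frag[e + 1] = base + j + 1  # q-side fragment
            end_pos[e] = sp[start + j]
            end_pos[e + 1] = sp[start + j]
        start = stop

    if all_copies:
        for c in range(len(copy_length)):
            if c not in set(hit_copies):
                frag_copy.append(c)
                frag_lo.append(0.0)
                frag_hi.append(float(copy_length[c]))

    frag_copy = np.array(frag_copy, dtype=np.int64)
    frag_lo = np.array(frag_lo)
    frag_hi = np.array(frag_hi)
    cen = copy_centromere[frag_copy]
    # centromere tie at a CL position goes to the p-side fragment
    frag_centric = (frag_lo < cen) & (cen <= frag_hi)
    return frag_copy, frag_lo, frag_hi, frag_centric, end_frag, end_pos


def _match_ends(
    end_pos: np.ndarray,
    threshold: float,
    f: float,
    rng: np.random.Generator,
    marked: Optional[np.ndarray] = None,
) -> list[tuple[int, int]]:
    """Random maximal matching of free ends under the step function.

    Each end is first marked un-rejoinable with probability f.  Then a
    uniformly random end with at least one available partner within the
    threshold is joined to a uniformly random such partner, until no eligible
    pair remains.
    """
    n = len(end_pos)
    if n == 0:
        return []
    if marked is None:
        marked = rng.random(n) < f
    avail = ~marked
    if avail.sum() < 2:
        return []
    d2 = np.sum((end_pos[:, None, :] - end_pos[None, :, :]) ** 2, axis=-1)
    adj = d2 <= threshold * threshold
    np.fill_diagonal(adj, False)
    adj &= avail[None, :] & avail[:, None]

    pairs = np.argwhere(np.triu(adj, 1))
    if len(pairs) == 0:
        return []
    partners: dict[int, list[int]] = {}
    for a, b in pairs:
        partners.setdefault(int(a), []).append(int(b))
        partners.setdefault(int(b), []).append(int(a))

    cnt = adj.sum(axis=1)
    junctions: list[tuple[int, int]] = []
    idx = np.arange(n)
    while True:
        cand = idx[avail & (cnt > 0)]
        if cand.size == 0:
            break
        a = int(cand[rng.integers(cand.size)])
        ps = [j for j in partners[a] if avail[j]]
        b = ps[int(rng.integers(len(ps)))]
        junctions.append((a, b))
        for e in (a, b):
            avail[e] = False
            for j in partners.get(e, ()):  # pragma: no branch
                cnt[j] -= 1
    return junctions


def _score_elements(
    frag_centric: np.ndarray,
    frag_len: np.ndarray,
    end_frag: np.ndarray,
    junctions: Sequence[tuple[int, int]],
    visibility_mbp: float,
) -> tuple[int, int, int]:
    """Assemble rearranged elements and count lethal aberration types.

    Elements are chains (open) or cycles (closed) of fragments linked by
    junctions.  An element with k >= 2 centromeres scores k-1 dicentrics; a
    closed element with exactly one centromere is a centric ring; any
    acentric element with total content >= the visibility threshold is a
    large deletion.
    """
    nf = len(frag_centric)
    # per-fragment adjacency through junctions
    adj: dict[int, list[int]] = {}
    deg = np.zeros(nf, dtype=np.int64)
    for e1, e2 in junctions:
        f1, f2 = int(end_frag[e1]), int(end_frag[e2])
        if e1 == e2:
            raise IonRbeError("junction joins an end to itself")
        adj.setdefault(f1, []).append(f2)
        adj.setdefault(f2, []).append(f1)
        deg[f1] += 1
        deg[f2] += 1

    dic = rings = dels = 0
    visited = np.zeros(nf, dtype=bool)
    for f0 in range(nf):
        if visited[f0]:
            continue
        # walk the component
        comp = [f0]
        visited[f0] = True
        stack = [f0]
        while stack:
            f = stack.pop()
            for g in adj.get(f, ()):  # pragma: no branch
                if not visited[g]:
                    visited[g] = True
                    comp.append(g)
                    stack.append(g)
        edges = sum(deg[f] for f in comp) // 2
        closed = edges == len(comp) and edges > 0  # cycle (incl. self-ring)
        ncent = int(frag_centric[comp].sum())
        content = float(frag_len[comp].sum())
        if ncent >= 2:
            dic += ncent - 1
        elif closed and ncent == 1:
            rings += 1
        if ncent == 0 and content >= visibility_mbp:
            dels += 1
    return dic, rings, dels


def lethal_from_cls(
    cl_copy: np.ndarray,
    cl_genomic: np.ndarray,
    cl_pos: np.ndarray,
    copy_length: np.ndarray,
    copy_centromere: np.ndarray,
    threshold_um: float,
    f: float,
    visibility_mbp: float,
    rng: np.random.Generator,
) -> bool:
    """Full per-cell pipeline on arrays: fragment, rejoin, score, decide."""
    if len(cl_copy) == 0:
        return False
    fc, lo, hi, cent, end_frag, end_pos = _fragment_arrays(
        cl_copy, cl_genomic, cl_pos, copy_length, copy_centromere
    )
    junctions = _match_ends(end_pos, threshold_um, f, rng)
    dic, rings, dels = _score_elements(cent, hi - lo, end_frag, junctions, visibility_mbp)
    return (dic + rings + dels) >= 1


# ---------------------------------------------------------------------------
# object API
# ---------------------------------------------------------------------------

def fragment(
    cls_: Sequence[CriticalLesion],
    config: TerritoryConfiguration,
) -> list[Fragment]:
    """Cut every chromosome copy at its CL positions.

    A copy hit by k CLs yields k+1 fragments; each CL contributes one free
    end (at the CL position) to each of its two flanking fragments.  Unhit
    copies are returned as single endless fragments.
    """
    cl_copy = np.array([c.copy for c in cls_], dtype=np.int64)
    cl_genomic = np.array([c.genomic_mbp for c in cls_])
    cl_pos = np.array([c.position for c in cls_]).reshape(-1, 3)
    fc, lo, hi, cent, end_frag, end_pos = _fragment_arrays(
        cl_copy,
        cl_genomic,
        cl_pos,
        config.copy_length_mbp,
        config.copy_centromere_mbp,
        all_copies=True,
    )
    ends_by_frag: dict[int, list[int]] = {}
    for e, fr in enumerate(end_frag):
        ends_by_frag.setdefault(int(fr), []).append(e)
    out = []
    for i in range(len(fc)):
        eids = tuple(ends_by_frag.get(i, ()))
        out.append(
            Fragment(
                copy=int(fc[i]),
                lo_mbp=float(lo[i]),
                hi_mbp=float(hi[i]),
                centric=bool(cent[i]),
                end_ids=eids,
                end_positions=tuple(tuple(map(float, end_pos[e])) for e in eids),
            )
        )
    return out


def _collect_ends(fragments: Sequence[Fragment]) -> tuple[np.ndarray, np.ndarray]:
    """(end positions, end->fragment index) for a fragment list."""
    n_ends = sum(len(fr.end_ids) for fr in fragments)
    pos = np.empty((n_ends, 3))
    end_frag = np.empty(n_ends, dtype=np.int64)
    seen = set()
    for i, fr in enumerate(fragments):
        for eid, ep in zip(fr.end_ids, fr.end_positions):
            if eid in seen or not (0 <= eid < n_ends):
                raise IonRbeError("fragment end ids must be unique and dense")
            seen.add(eid)
            pos[eid] = ep
            end_frag[eid] = i
    return pos, end_frag


def rejoin(
    fragments: Sequence[Fragment],
    params: RejoiningParameters,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random maximal matching of free ends within the threshold distance."""
    if params.threshold_um is None:
        raise ConfigurationError("rejoin requires a resolved threshold distance")
    end_pos, _ = _collect_ends(fragments)
    return _match_ends(end_pos, params.threshold_um, params.f, rng)


def assemble_and_score(
    fragments: Sequence[Fragment],
    junctions: Sequence[tuple[int, int]],
    visibility_threshold_mbp: float = DEFAULT_VISIBILITY_MBP,
) -> AberrationTally:
    """Score dicentrics, centric rings, and large deletions."""
    _, end_frag = _collect_ends(fragments)
    ends_used = [e for j in junctions for e in j]
    if len(set(ends_used)) != len(ends_used):
        raise IonRbeError("inconsistent junction set: an end is reused")
    cent = np.array([fr.centric for fr in fragments], dtype=bool)
    lens = np.array([fr.length_mbp for fr in fragments])
    dic, rings, dels = _score_elements(
        cent, lens, end_frag, junctions, visibility_threshold_mbp
    )
    return AberrationTally(dicentrics=dic, centric_rings=rings, large_deletions=dels)
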