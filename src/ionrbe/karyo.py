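"""Cell-nucleus geometry, interphase chromosome territories, and arm domains.

The nucleus is voxelized and partitioned into one compact territory per
chromosome copy, with territory volume proportional to chromosome DNA content
(Mbp).  Each territory carries a one-dimensional genomic embedding: its voxels
are ordered along a spatially local walk that is mapped linearly onto the
genomic coordinate (0, length), so that any point in the nucleus resolves to a
(chromosome copy, arm, genomic position) triple.  The mean centre-to-centre
distance between face-adjacent territories defines the rejoining threshold
used by the aberration module.
"""

from __future__ import annotations

import importlib.resources
from collections import deque
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import ConfigurationError, OutOfNucleusError, UndefinedThresholdError

__all__ = [
    "Chromosome",
    "Karyotype",
    "NucleusGeometry",
    "TerritoryConfiguration",
    "build_territories",
    "threshold_distance",
    "locate",
    "load_karyotype",
    "human_karyotype",
    "toy_karyotype",
]

# weights of a low-discrepancy projection used to derive a deterministic
# sub-voxel genomic offset from a continuous position (breaks genomic ties
# between lesions falling in the same voxel)
_SUBVOXEL_W = (0.6180339887498949, 0.3247179572447461, 0.1225611668766536)


@dataclass(frozen=True)
class Chromosome:
    """One chromosome type: length and centromere offset in Mbp."""

    name: str
    length_mbp: float
    centromere_mbp: float
    copies: int = 1

    def __post_init__(self) -> None:
        if self.length_mbp <= 0:
            raise ConfigurationError(f"{self.name}: length must be positive")
        if not (0 < self.centromere_mbp < self.length_mbp):
            raise ConfigurationError(
                f"{self.name}: centromere must lie strictly inside (0, length)"
            )
        if self.copies < 1:
            raise ConfigurationError(f"{self.name}: copies must be >= 1")


@dataclass(frozen=True)
class Karyotype:
    """Chromosome content of the cell.

    ``copies`` allows diploid (or aneuploid) karyotypes without repeating
    rows; each copy receives its own spatial territory.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("karyotype must contain at least one chromosome")

    @property
    def n_copies(self) -> int:
        return sum(c.copies for c in self.chromosomes)

    @property
    def genome_mbp(self) -> float:
        return float(sum(c.length_mbp * c.copies for c in self.chromosomes))

    def expanded(self) -> list[Chromosome]:
        """One entry per chromosome *copy*, in stable order."""
        out: list[Chromosome] = []
        for c in self.chromosomes:
            out.extend([c] * c.copies)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Karyotype":
        chroms = tuple(
            Chromosome(
                name=str(r["name"]),
                length_mbp=float(r["length_mbp"]),
                centromere_mbp=float(r["centromere_mbp"]),
                copies=int(r.get("copies", 1)),
            )
            for _, r in df.iterrows()
        )
        return cls(chroms)


def load_karyotype(path) -> Karyotype:
    """Read a karyotype CSV with header ``name,length_mbp,centromere_mbp,copies``."""
    return Karyotype.from_frame(pd.read_csv(path, comment="#"))


def _packaged(name: str):
    return importlib.resources.files("ionrbe.data").joinpath(name)


def human_karyotype() -> Karyotype:
    """Packaged diploid human (46,XX) karyotype, hg38 chromosome sizes."""
    return load_karyotype(_packaged("human_karyotype.csv"))


def toy_karyotype() -> Karyotype:
    """Small two-chromosome karyotype used for fast tests and examples."""
    return load_karyotype(_packaged("toy_karyotype.csv"))


@dataclass(frozen=True)
class NucleusGeometry:
    """Nucleus shape and voxelization.

    The beam axis coincides with the cylinder axis (z).  Default: upright
    cylinder of 6 um radius and 6 um height, the geometry used for the
    chordoma radiosensitivity database.
    """

    shape: str = "cylinder"
    radius_um: float = 6.0
    height_um: float = 6.0
    voxel_um: float = 0.25

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere"):
            raise ConfigurationError(f"unknown nucleus shape {self.shape!r}")
        if self.radius_um <= 0:
            raise ConfigurationError("radius must be positive")
        if self.shape == "cylinder" and self.height_um <= 0:
            raise ConfigurationError("cylinder height must be positive")
        if not (0 < self.voxel_um <= self.radius_um / 4):
            raise ConfigurationError("voxel size must be in (0, radius/4]")

    @property
    def height(self) -> float:
        """Axial extent in um (diameter for a sphere)."""
        return self.height_um if self.shape == "cylinder" else 2 * self.radius_um

    @property
    def volume_um3(self) -> float:
        if self.shape == "cylinder":
            return float(np.pi * self.radius_um**2 * self.height_um)
        return float(4.0 / 3.0 * np.pi * self.radius_um**3)

    @property
    def cross_section_um2(self) -> float:
        """Beam-facing cross-sectional area (tracks travel along z)."""
        return float(np.pi * self.radius_um**2)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized inside test for an (n, 3) array of um coordinates."""
        p = np.atleast_2d(points)
        if self.shape == "cylinder":
            r2 = p[:, 0] ** 2 + p[:, 1] ** 2
            return (r2 <= self.radius_um**2) & (p[:, 2] >= 0) & (p[:, 2] <= self.height_um)
        c = np.array([0.0, 0.0, self.radius_um])
        return np.sum((p - c) ** 2, axis=1) <= self.radius_um**2

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points uniform in the nucleus volume."""
        if self.shape == "cylinder":
            r = self.radius_um * np.sqrt(rng.random(n))
            th = rng.random(n) * 2 * np.pi
            z = rng.random(n) * self.height_um
            return np.column_stack([r * np.cos(th), r * np.sin(th), z])
        # sphere centred at (0, 0, R)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = self.radius_um * rng.random(n) ** (1 / 3)
        return v * r[:, None] + np.array([0.0, 0.0, self.radius_um])


class TerritoryConfiguration:
    """A voxel partition of the nucleus into chromosome-copy territories.

    Attributes
    ----------
    copy_id : (nvox,) int32
        Flat-grid map voxel -> chromosome copy (-1 outside the nucleus).
    walk_rank : (nvox,) int32
        Position of the voxel along its territory's genomic walk.
    centers : (n_copies, 3) float
        Territory centroids in um.
    adjacency : frozenset of (i, j)
        Unordered pairs of copies sharing at least one voxel face.
    """

    def __init__(
        self,
        karyotype: Karyotype,
        geometry: NucleusGeometry,
        shape_vox: tuple[int, int, int],
        origin: np.ndarray,
        copy_id: np.ndarray,
        walk_rank: np.ndarray,
        centers: np.ndarray,
        adjacency: frozenset,
        seed: int,
    ) -> None:
        self.karyotype = karyotype
        self.geometry = geometry
        self.shape_vox = shape_vox
        self.origin = origin
        self.copy_id = copy_id
        self.walk_rank = walk_rank
        self.centers = centers
        self.adjacency = adjacency
        self.seed = seed
        copies = karyotype.expanded()
        self.copy_length_mbp = np.array([c.length_mbp for c in copies])
        self.copy_centromere_mbp = np.array([c.centromere_mbp for c in copies])
        self.copy_names = [c.name for c in copies]
        self.n_copies = len(copies)
        self.copy_voxel_count = np.bincount(
            copy_id[copy_id >= 0], minlength=self.n_copies
        ).astype(np.int64)

    # ---- voxel helpers -------------------------------------------------
    def _voxel_index(self, points: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape_vox
        ijk = np.floor((points - self.origin) / self.geometry.voxel_um).astype(np.int64)
        ijk[:, 0] = np.clip(ijk[:, 0], 0, nx - 1)
        ijk[:, 1] = np.clip(ijk[:, 1], 0, ny - 1)
        ijk[:, 2] = np.clip(ijk[:, 2], 0, nz - 1)
        return (ijk[:, 0] * ny + ijk[:, 1]) * nz + ijk[:, 2]

    def locate_arrays(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map (n, 3) um points to (copy, arm, genomic Mbp) arrays.

        arm is 0 for the p-arm (position < centromere) and 1 for the q-arm.
        Points inside the nucleus but in an unassigned boundary voxel are
        snapped to the nearest assigned voxel centre.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.geometry.contains(points)
        if not np.all(inside):
            raise OutOfNucleusError("point outside the nucleus volume")
        vox = self._voxel_index(points)
        cid = self.copy_id[vox]
        bad = np.nonzero(cid < 0)[0]
        if bad.size:
            vox = vox.copy()
            vox[bad] = self._snap(points[bad])
            cid = self.copy_id[vox]
        rank = self.walk_rank[vox].astype(float)
        # deterministic sub-voxel offset in [0, 1)
        frac = (points / self.geometry.voxel_um) % 1.0
        u = (frac @ np.array(_SUBVOXEL_W)) % 1.0
        count = self.copy_voxel_count[cid].astype(float)
        genomic = (rank + u) / count * self.copy_length_mbp[cid]
        arm = (genomic >= self.copy_centromere_mbp[cid]).astype(np.int8)
        return cid, arm, genomic

    def _snap(self, points: np.ndarray) -> np.ndarray:
        """Nearest assigned voxel for boundary points (brute force, rare)."""
        if not hasattr(self, "_assigned_centers"):
            idx = np.nonzero(self.copy_id >= 0)[0]
            self._assigned_idx = idx
            self._assigned_centers = self.voxel_centers(idx)
        out = np.empty(len(points), dtype=np.int64)
        for i, p in enumerate(points):
            d2 = np.sum((self._assigned_centers - p) ** 2, axis=1)
            out[i] = self._assigned_idx[int(np.argmin(d2))]
        return out

    def voxel_centers(self, flat_idx: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape_vox
        k = flat_idx % nz
        j = (flat_idx // nz) % ny
        i = flat_idx // (ny * nz)
        ijk = np.column_stack([i, j, k]).astype(float)
        return self.origin + (ijk + 0.5) * self.geometry.voxel_um


def locate(config: TerritoryConfiguration, point) -> tuple[str, str, float]:
    """Resolve one point to (chromosome copy name, 'p'|'q', genomic Mbp)."""
    cid, arm, genomic = config.locate_arrays(np.asarray(point, dtype=float)[None, :])
    return config.copy_names[int(cid[0])], "pq"[int(arm[0])], float(genomic[0])


def threshold_distance(config: TerritoryConfiguration) -> float:
    """Mean Euclidean centre-to-centre distance over adjacent territory pairs.

    This is the step-function rejoining threshold: fragment ends farther
    apart than this distance never rejoin.
    """
    if not config.adjacency:
        raise UndefinedThresholdError(
            "single-territory configuration has no adjacent pairs"
        )
    pairs = np.array(sorted(config.adjacency))
    d = np.linalg.norm(config.centers[pairs[:, 0]] - config.centers[pairs[:, 1]], axis=1)
    return float(d.mean())


# ---------------------------------------------------------------------------
# territory construction
# ---------------------------------------------------------------------------

def _grid(geometry: NucleusGeometry):
    vs = geometry.voxel_um
    R = geometry.radius_um
    H = geometry.height
    nx = ny = int(np.ceil(2 * R / vs))
    nz = int(np.ceil(H / vs))
    origin = np.array([-R, -R, 0.0])
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * vs
    inside = geometry.contains(centers.reshape(-1, 3)).reshape(nx, ny, nz)
    return (nx, ny, nz), origin, inside


def _neighbor_table(shape_vox, inside_flat: np.ndarray) -> np.ndarray:
    """(nvox, 6) face-neighbour flat indices, -1 where absent/outside."""
    nx, ny, nz = shape_vox
    n = nx * ny * nz
    idx = np.arange(n)
    k = idx % nz
    j = (idx // nz) % ny
    i = idx // (ny * nz)
    nbr = np.full((n, 6), -1, dtype=np.int64)
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for s, (di, dj, dk) in enumerate(steps):
        i2, j2, k2 = i + di, j + dj, k + dk
        ok = (i2 >= 0) & (i2 < nx) & (j2 >= 0) & (j2 < ny) & (k2 >= 0) & (k2 < nz)
        f = (i2 * ny + j2) * nz + k2
        ok &= inside_flat[np.where(ok, f, 0)]
        nbr[ok, s] = f[ok]
    return nbr


def build_territories(
    karyotype: Karyotype,
    geometry: NucleusGeometry,
    seed: int,
) -> TerritoryConfiguration:
    """Partition the voxelized nucleus into chromosome territories.

    Territories grow from uniformly sampled seed voxels by synchronized
    breadth-first accretion with per-copy quotas proportional to chromosome
    Mbp, producing compact domains whose volumes track DNA content.  Each
    territory's voxels are then ordered by a locality-preserving
    nearest-neighbour walk that defines the genomic coordinate along the
    territory.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    shape_vox, origin, inside = _grid(geometry)
    nx, ny, nz = shape_vox
    inside_flat = inside.ravel()
    in_idx = np.nonzero(inside_flat)[0]
    n_in = in_idx.size
    copies = karyotype.expanded()
    n_copies = len(copies)
    lengths = np.array([c.length_mbp for c in copies])

    # integer targets proportional to Mbp (largest-remainder apportionment)
    raw = lengths / lengths.sum() * n_in
    targets = np.floor(raw).astype(np.int64)
    rem = n_in - targets.sum()
    if rem:
        order = np.argsort(-(raw - np.floor(raw)))
        targets[order[:rem]] += 1
    if np.any(targets < 8):
        raise ConfigurationError(
            "voxelization too coarse: smallest territory would get "
            f"{int(targets.min())} voxels (< 8); reduce voxel size"
        )

    nbr = _neighbor_table(shape_vox, inside_flat)
    copy_id = np.full(nx * ny * nz, -1, dtype=np.int32)

    seeds = _spaced_seeds(
        in_idx, targets, shape_vox, origin, geometry.voxel_um, rng
    )
    frontiers = [deque([int(s)]) for s in seeds]
    claimed = np.zeros(n_copies, dtype=np.int64)
    claim_order: list[list[int]] = [[] for _ in range(n_copies)]

    def claim(c: int, v: int) -> None:
        copy_id[v] = c
        claimed[c] += 1
        claim_order[c].append(v)
        for w in nbr[v]:
            if w >= 0 and copy_id[w] < 0:
                frontiers[c].append(int(w))

    for c, s in enumerate(seeds):
        frontiers[c].popleft()
        claim(c, int(s))

    # synchronized accretion: always grow the territory with the smallest
    # fractional progress claimed/target (random infinitesimal tie-break),
    # which keeps all territories at equal relative size as they expand and
    # minimises enclosure of small territories by large neighbours
    key = claimed / targets + rng.random(n_copies) * 1e-9
    blocked = np.zeros(n_copies, dtype=bool)
    remaining = int(n_in - claimed.sum())
    while remaining > 0:
        k = key.copy()
        k[blocked] = np.inf
        c = int(np.argmin(k))
        if not np.isfinite(k[c]):
            # disconnected pockets: attach each orphan to nearest claimed voxel
            orphan = in_idx[copy_id[in_idx] < 0]
            done = np.nonzero(copy_id >= 0)[0]
            oc = _voxel_centers(shape_vox, origin, geometry.voxel_um, orphan)
            dc = _voxel_centers(shape_vox, origin, geometry.voxel_um, done)
            for o, p in zip(orphan, oc):
                j = int(np.argmin(np.sum((dc - p) ** 2, axis=1)))
                claim(int(copy_id[done[j]]), int(o))
                remaining -= 1
            break
        fr = frontiers[c]
        got = False
        while fr:
            v = fr.popleft()
            if copy_id[v] < 0:
                claim(c, v)
                remaining -= 1
                got = True
                break
        if got:
            key[c] = claimed[c] / targets[c] + (key[c] % 1e-9)
        else:
            blocked[c] = True

    _rebalance(copy_id, nbr, in_idx, claimed, targets, rng)

    # genomic walk and ranks
    walk_rank = np.full(nx * ny * nz, -1, dtype=np.int32)
    centers = np.empty((n_copies, 3))
    for c in range(n_copies):
        vox = np.nonzero(copy_id == c)[0]
        pts = _voxel_centers(shape_vox, origin, geometry.voxel_um, vox)
        centers[c] = pts.mean(axis=0)
        start = int(seeds[c])
        if copy_id[start] != c:  # seed lost in rebalancing: restart at centroid
            start = int(vox[np.argmin(np.sum((pts - centers[c]) ** 2, axis=1))])
        order = _nn_walk(vox, shape_vox, start)
        walk_rank[order] = np.arange(len(order), dtype=np.int32)

    # face adjacency between copies
    adj: set[tuple[int, int]] = set()
    grid = copy_id.reshape(nx, ny, nz)
    for axis in range(3):
        a = np.take(grid, np.arange(grid.shape[axis] - 1), axis=axis).ravel()
        b = np.take(grid, np.arange(1, grid.shape[axis]), axis=axis).ravel()
        m = (a >= 0) & (b >= 0) & (a != b)
        for x, y in zip(a[m], b[m]):
            adj.add((int(min(x, y)), int(max(x, y))))

    return TerritoryConfiguration(
        karyotype,
        geometry,
        shape_vox,
        origin,
        copy_id,
        walk_rank,
        centers,
        frozenset(adj),
        seed,
    )


def _spaced_seeds(
    in_idx: np.ndarray,
    targets: np.ndarray,
    shape_vox,
    origin,
    vs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One seed voxel per copy, spaced roughly by equivalent-sphere radii.

    Seeds are drawn uniformly but rejected (up to a retry budget) when closer
    to an already placed seed than 0.7 x the sum of the two territories'
    equivalent radii; larger territories are placed first.
    """
    n = len(targets)
    radii = (3.0 * targets * vs**3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    order = np.argsort(-targets)
    seeds = np.empty(n, dtype=np.int64)
    placed_pts: list[np.ndarray] = []
    placed_r: list[float] = []
    taken: set[int] = set()
    for c in order:
        best, best_d = -1, -1.0
        for _ in range(40):
            v = int(in_idx[rng.integers(len(in_idx))])
            if v in taken:
                continue
            p = _voxel_centers(shape_vox, origin, vs, np.array([v]))[0]
            if not placed_pts:
                best = v
                break
            d = min(
                float(np.linalg.norm(p - q)) / (0.7 * (radii[c] + r))
                for q, r in zip(placed_pts, placed_r)
            )
            if d >= 1.0:
                best = v
                break
            if d > best_d:
                best, best_d = v, d
        seeds[c] = best
        taken.add(best)
        placed_pts.append(_voxel_centers(shape_vox, origin, vs, np.array([best]))[0])
        placed_r.append(float(radii[c]))
    return seeds


def _rebalance(
    copy_id: np.ndarray,
    nbr: np.ndarray,
    in_idx: np.ndarray,
    claimed: np.ndarray,
    targets: np.ndarray,
    rng: np.random.Generator,
    tol: float = 0.05,
    max_sweeps: int = 30,
) -> None:
    """Move boundary voxels from over- to under-target territories in place.

    Growth can enclose a territory before it reaches its Mbp-proportional
    quota; sweeping the inter-territory boundary restores volume
    proportionality while keeping transfers face-adjacent to the receiving
    territory (which stays connected).
    """
    margin = 0.02
    for _ in range(max_sweeps):
        rel = (claimed - targets) / targets
        if np.all(np.abs(rel) <= tol):
            break
        own = copy_id[in_idx]
        nb_own = np.where(nbr[in_idx] >= 0, copy_id[nbr[in_idx]], own[:, None])
        boundary = np.any((nb_own >= 0) & (nb_own != own[:, None]), axis=1)
        cand = in_idx[boundary]
        moved = 0
        for v in cand[rng.permutation(len(cand))]:
            a = copy_id[v]
            # steepest-descent transfer: give the voxel to the adjacent
            # territory with the largest relative deficit w.r.t. this one,
            # letting volume diffuse through intermediate territories
            best_b, best_gap = -1, margin
            for w in nbr[v]:
                if w < 0:
                    continue
                b = copy_id[w]
                if b >= 0 and b != a and rel[a] - rel[b] > best_gap:
                    best_b, best_gap = b, rel[a] - rel[b]
            if best_b >= 0:
                copy_id[v] = best_b
                claimed[a] -= 1
                claimed[best_b] += 1
                rel[a] = (claimed[a] - targets[a]) / targets[a]
                rel[best_b] = (claimed[best_b] - targets[best_b]) / targets[best_b]
                moved += 1
        if moved == 0:
            break


def _voxel_centers(shape_vox, origin, vs, flat_idx):
    nx, ny, nz = shape_vox
    k = flat_idx % nz
    j = (flat_idx // nz) % ny
    i = flat_idx // (ny * nz)
    return origin + (np.column_stack([i, j, k]) + 0.5) * vs


# neighbour offset shells used by the genomic walk: faces, then edges, then
# corners of the 3x3x3 cube around the current voxel
_SHELLS = []
_face, _edge, _corner = [], [], []
for _di in (-1, 0, 1):
    for _dj in (-1, 0, 1):
        for _dk in (-1, 0, 1):
            _o = abs(_di) + abs(_dj) + abs(_dk)
            if _o == 1:
                _face.append((_di, _dj, _dk))
            elif _o == 2:
                _edge.append((_di, _dj, _dk))
            elif _o == 3:
                _corner.append((_di, _dj, _dk))
_SHELLS = [_face, _edge, _corner]


def _nn_walk(vox: np.ndarray, shape_vox, start: int) -> np.ndarray:
    """Order a territory's voxels by a greedy nearest-neighbour walk.

    Prefers face, then edge, then corner neighbours; falls back to the
    nearest unvisited voxel (Euclidean) when the walk is locally stranded.
    """
    nx, ny, nz = shape_vox
    vset = {}
    k = vox % nz
    j = (vox // nz) % ny
    i = vox // (ny * nz)
    coords = {int(v): (int(a), int(b), int(c)) for v, a, b, c in zip(vox, i, j, k)}
    unvisited = set(int(v) for v in vox)
    order = np.empty(len(vox), dtype=np.int64)
    cur = start
    unvisited.discard(cur)
    order[0] = cur
    for t in range(1, len(vox)):
        ci, cj, ck = coords[cur]
        nxt = -1
        for shell in _SHELLS:
            for di, dj, dk in shell:
                cand = ((ci + di) * ny + (cj + dj)) * nz + (ck + dk)
                if cand in unvisited:
                    nxt = cand
                    break
            if nxt >= 0:
                break
        if nxt < 0:
            # stranded: jump to nearest remaining voxel
            rem = np.fromiter(unvisited, dtype=np.int64)
            rk = rem % nz
            rj = (rem // nz) % ny
            ri = rem // (ny * nz)
            d2 = (ri - ci) ** 2 + (rj - cj) ** 2 + (rk - ck) ** 2
            nxt = int(rem[int(np.argmin(d2))])
        unvisited.discard(nxt)
        order[t] = nxt
        cur = nxt
    return order
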