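"""Blade segmentation, blade-on-blade superposition and motif-position assignment.

A WD40 propeller is built from (typically eight) blades, each a four-stranded
antiparallel beta-sheet.  Strands are found from main-chain hydrogen-bond
ladders, grouped into blades by ladder connectivity, superposed pairwise by
least squares, and the resulting residue correspondence is numbered as motif
positions 1-32, calibrated so that the conserved aspartate column is
position 26 (which places the tetrad His/Ser-Thr/Trp on 4/22/32).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import DomainStructure
from .tetrads import detect_hbonds

__all__ = [
    "BladeSegmentation",
    "SuperpositionResult",
    "MotifAlignment",
    "SegmentationError",
    "CalibrationError",
    "segment_blades",
    "superpose_blades",
    "assign_motif_positions",
    "kabsch_superpose",
    "format_alignment",
]

MOTIF_LENGTH = 32
ASP_POSITION = 26  # the conserved aspartate column anchors the numbering


class SegmentationError(ValueError):
    """Automatic blade detection failed; user ranges are advised."""


class CalibrationError(ValueError):
    """No aspartate-consensus column found (domain may not be WD40)."""


@dataclass(frozen=True)
class BladeSegmentation:
    """Ordered, non-overlapping inclusive residue ranges, one per blade."""

    blades: tuple[tuple[int, int], ...]
    provenance: str = "auto"  # auto | user

    def __post_init__(self):
        prev_end = None
        for start, end in self.blades:
            if start > end:
                raise ValueError(f"invalid blade range [{start}, {end}]")
            if prev_end is not None and start <= prev_end:
                raise ValueError("blade ranges must be ascending and non-overlapping")
            prev_end = end
        if len(self.blades) < 4:
            raise ValueError(f"a propeller needs >=4 blades, got {len(self.blades)}")

    @property
    def n_blades(self) -> int:
        return len(self.blades)

    def blade_of(self, residue_number: int) -> int | None:
        """1-based blade index containing the residue, else None."""
        for i, (start, end) in enumerate(self.blades, start=1):
            if start <= residue_number <= end:
                return i
        return None


@dataclass(frozen=True)
class SuperpositionResult:
    pairwise_rmsd: np.ndarray  # (n, n), Angstrom, symmetric, zero diagonal
    correspondences: dict[tuple[int, int], tuple[tuple[int, int], ...]]
    # key (i, j) with i < j, 1-based blade indices; values (res_i, res_j) pairs


@dataclass(frozen=True)
class MotifAlignment:
    """Residue -> (blade index 1-based, motif position 1-32) for aligned residues."""

    assignments: dict[int, tuple[int, int]]
    reference_blade: int

    def position_of(self, residue_number: int) -> int | None:
        a = self.assignments.get(residue_number)
        return None if a is None else a[1]

    def blade_of(self, residue_number: int) -> int | None:
        a = self.assignments.get(residue_number)
        return None if a is None else a[0]

    def residues_at_position(self, position: int) -> list[int]:
        return sorted(n for n, (_, p) in self.assignments.items() if p == position)


# --- segmentation -----------------------------------------------------------

def segment_blades(domain: DomainStructure,
                   user_ranges: list[tuple[int, int]] | None = None,
                   min_strand_len: int = 3) -> BladeSegmentation:
    """Detect blades, or validate user-supplied ranges (the authoritative path).

    Auto mode: main-chain hydrogen-bond ladders define beta-strands (runs of
    >=3 consecutive ladder-paired residues); strands connected by ladder rungs
    form one blade; blades are reported in sequence order as inclusive ranges
    spanning their strands.
    """
    if user_ranges is not None:
        return BladeSegmentation(blades=tuple(tuple(r) for r in user_ranges),
                                 provenance="user")

    rungs = detect_hbonds(domain, selection="mainchain_only")
    partners: dict[int, set[int]] = {}
    for b in rungs:
        i, j = b.donor[0], b.acceptor[0]
        partners.setdefault(i, set()).add(j)
        partners.setdefault(j, set()).add(i)

    # strands: maximal runs of consecutive resolved residues that are paired
    resolved = sorted(r.author_number for r in domain.residues)
    strands: list[tuple[int, int]] = []
    run: list[int] = []
    for n in resolved:
        if n in partners and (not run or n == run[-1] + 1):
            run.append(n)
        else:
            if len(run) >= min_strand_len:
                strands.append((run[0], run[-1]))
            run = [n] if n in partners else []
    if len(run) >= min_strand_len:
        strands.append((run[0], run[-1]))

    if not strands:
        raise SegmentationError("no beta-strands detected; supply blade ranges")

    def strand_of(num: int) -> int | None:
        for k, (s, e) in enumerate(strands):
            if s <= num <= e:
                return k
        return None

    # union strands connected by ladder rungs
    parent = list(range(len(strands)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in rungs:
        si, sj = strand_of(b.donor[0]), strand_of(b.acceptor[0])
        if si is not None and sj is not None and si != sj:
            parent[find(si)] = find(sj)

    groups: dict[int, list[int]] = {}
    for k in range(len(strands)):
        groups.setdefault(find(k), []).append(k)

    ranges = []
    for members in groups.values():
        if len(members) < 2:
            continue  # an isolated paired run is not a blade
        start = min(strands[k][0] for k in members)
        end = max(strands[k][1] for k in members)
        ranges.append((start, end))
    ranges.sort()
    if len(ranges) < 4:
        raise SegmentationError(
            f"auto-detection found {len(ranges)} blades (<4); supply blade ranges"
        )
    return BladeSegmentation(blades=tuple(ranges), provenance="auto")


# --- superposition ----------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` with ``R @ mobile_i + t ~ target_i`` (closed-form
    SVD solution, proper rotation enforced).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def _ordered_match(moved: np.ndarray, nums_a: list[int],
                   target: np.ndarray, nums_b: list[int],
                   cutoff: float = 4.5) -> list[tuple[int, int]]:
    """Max-score sequence-order-preserving matching of spatially close CAs."""
    na, nb = len(nums_a), len(nums_b)
    d = np.linalg.norm(moved[:, None, :] - target[None, :, :], axis=-1)
    score = np.where(d <= cutoff, cutoff - d, -np.inf)
    # DP over pairs: best[i][j] = best score using a[:i], b[:j]
    best = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            take = best[i - 1][j - 1] + score[i - 1, j - 1] if np.isfinite(score[i - 1, j - 1]) else -np.inf
            best[i][j] = max(best[i - 1][j], best[i][j - 1], take)
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if np.isfinite(score[i - 1, j - 1]) and np.isclose(
                best[i][j], best[i - 1][j - 1] + score[i - 1, j - 1]):
            pairs.append((nums_a[i - 1], nums_b[j - 1]))
            i, j = i - 1, j - 1
        elif best[i - 1][j] >= best[i][j - 1]:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def superpose_blades(domain: DomainStructure, blades: BladeSegmentation,
                     cutoff: float = 4.5, n_iter: int = 3) -> SuperpositionResult:
    """Pairwise least-squares superposition of all blades on CA atoms.

    Correspondences come from sequence-order dynamic programming over
    spatially compatible CA pairs (<= *cutoff* after superposition), iterated
    with re-superposition.  Blades with <4 CA atoms are skipped with a warning.
    """
    n = blades.n_blades
    coords: list[tuple[list[int], np.ndarray]] = []
    for (start, end) in blades.blades:
        nums, xyz = [], []
        for r in domain.residues:
            if start <= r.author_number <= end:
                a = r.atom("CA")
                if a is not None:
                    nums.append(r.author_number)
                    xyz.append(a.position)
        coords.append((nums, np.array(xyz) if xyz else np.empty((0, 3))))

    rmsd = np.zeros((n, n))
    corr: dict[tuple[int, int], tuple[tuple[int, int], ...]] = {}
    for bi in range(n):
        for bj in range(bi + 1, n):
            nums_a, xa = coords[bi]
            nums_b, xb = coords[bj]
            if len(nums_a) < 4 or len(nums_b) < 4:
                warnings.warn(f"blade {bi + 1} or {bj + 1} has <4 CA atoms; pair skipped")
                rmsd[bi, bj] = rmsd[bj, bi] = np.nan
                continue
            # seed correspondence: truncate to common length from the start
            m = min(len(nums_a), len(nums_b))
            pairs = list(zip(nums_a[:m], nums_b[:m]))
            r = np.nan
            for _ in range(n_iter):
                ia = [nums_a.index(p) for p, _ in pairs]
                ib = [nums_b.index(q) for _, q in pairs]
                R, t, r = kabsch_superpose(xa[ia], xb[ib])
                moved = xa @ R.T + t
                new_pairs = _ordered_match(moved, nums_a, xb, nums_b, cutoff)
                if len(new_pairs) < 4 or new_pairs == pairs:
                    pairs = new_pairs if len(new_pairs) >= 4 else pairs
                    break
                pairs = new_pairs
            ia = [nums_a.index(p) for p, _ in pairs]
            ib = [nums_b.index(q) for _, q in pairs]
            _, _, r = kabsch_superpose(xa[ia], xb[ib])
            rmsd[bi, bj] = rmsd[bj, bi] = r
            corr[(bi + 1, bj + 1)] = tuple(pairs)
    return SuperpositionResult(pairwise_rmsd=rmsd, correspondences=corr)


# --- motif position assignment ---------------------------------------------

def _pair_map(superposition: SuperpositionResult, bi: int, bj: int) -> dict[int, int]:
    """Correspondence as a residue map blade bi -> blade bj (1-based indices)."""
    if (bi, bj) in superposition.correspondences:
        return dict(superposition.correspondences[(bi, bj)])
    if (bj, bi) in superposition.correspondences:
        return {b: a for a, b in superposition.correspondences[(bj, bi)]}
    return {}


def assign_motif_positions(blades: BladeSegmentation,
                           superposition: SuperpositionResult,
                           domain: DomainStructure) -> MotifAlignment:
    """Number aligned columns 1-32, anchored on the conserved aspartate column.

    The reference blade is the one participating in the most correspondence
    pairs (ties: lowest index).  The reference column whose members are most
    often aspartate becomes position 26; other positions follow by sequence
    offset within each blade (positions outside 1-32, and residues outside
    blades, stay unaligned).
    """
    n = blades.n_blades
    # reference blade: most aligned pairs overall
    counts = [0] * (n + 1)
    for (bi, bj), pairs in superposition.correspondences.items():
        counts[bi] += len(pairs)
        counts[bj] += len(pairs)
    ref = max(range(1, n + 1), key=lambda b: (counts[b], -b))

    maps_to_ref = {b: _pair_map(superposition, b, ref) for b in range(1, n + 1) if b != ref}

    def aa1(num: int) -> str:
        r = domain.residue(num)
        return "" if r is None else r.aa1

    # score each reference residue as a candidate aspartate column
    ref_start, ref_end = blades.blades[ref - 1]
    best_num, best_votes = None, -1
    for num in range(ref_start, ref_end + 1):
        if domain.residue(num) is None:
            continue
        votes = 1 if aa1(num) == "D" else 0
        for b, mapping in maps_to_ref.items():
            inv = {v: k for k, v in mapping.items()}
            partner = inv.get(num)
            if partner is not None and aa1(partner) == "D":
                votes += 1
        if votes > best_votes:
            best_num, best_votes = num, votes
    if best_num is None or best_votes < max(2, (n + 1) // 2):
        raise CalibrationError(
            "no aspartate-consensus column found; domain may not be a WD40 propeller"
        )
    ref_asp = best_num

    assignments: dict[int, tuple[int, int]] = {}

    def assign_blade(b: int, asp_num: int):
        # the full 1-32 window around the calibrated aspartate (position 26);
        # motif columns extend past the strand core into the blade shoulders
        for pos in range(1, MOTIF_LENGTH + 1):
            num = asp_num + pos - ASP_POSITION
            if domain.residue(num) is None or num in assignments:
                continue
            assignments[num] = (b, pos)

    assign_blade(ref, ref_asp)
    for b in range(1, n + 1):
        if b == ref:
            continue
        mapping = maps_to_ref[b]
        inv = {v: k for k, v in mapping.items()}
        asp_b = inv.get(ref_asp)
        if asp_b is None:
            # anchor on the most common sequence offset of the correspondence
            if not mapping:
                warnings.warn(f"blade {b}: no correspondence to reference; left unaligned")
                continue
            offsets = [q - p for p, q in mapping.items()]
            shift = int(np.median(offsets))
            asp_b = ref_asp - shift  # note mapping is b -> ref
        assign_blade(b, asp_b)

    return MotifAlignment(assignments=assignments, reference_blade=ref)


def format_alignment(motif: MotifAlignment, domain: DomainStructure) -> str:
    """Text alignment: one row per blade, columns = motif positions 1-32."""
    by_blade: dict[int, dict[int, int]] = {}
    for num, (b, pos) in motif.assignments.items():
        by_blade.setdefault(b, {})[pos] = num
    lines = ["          " + "".join(f"{p % 10}" for p in range(1, MOTIF_LENGTH + 1))]
    for b in sorted(by_blade):
        row = by_blade[b]
        nums = [row[p] for p in sorted(row)]
        cells = []
        for p in range(1, MOTIF_LENGTH + 1):
            if p in row:
                r = domain.residue(row[p])
                cells.append(r.aa1 if r else "-")
            else:
                cells.append("-")
        lines.append(f"{min(nums):>4}-{max(nums):<4} " + "".join(cells))
    return "\n".join(lines)
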