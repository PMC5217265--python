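"""LD-block candidate selection on a per-SNP p-value track.

The selection criterion targets loci where many neighbouring SNPs are
co-associated: a *block* is a maximal run of at least ``min_snps``
consecutive SNPs, each associated at p < ``p_block``, with every adjacent
pair closer than ``max_gap_bp`` on the same chromosome.  From each block the
*index SNPs* -- members below the stricter ``p_index`` threshold -- are taken
forward to individual-genotyping validation.  Candidate sets from the two
scan rounds are merged by SNP id with per-round provenance.

Strictness follows the criterion verbatim: "less than 30 kb" and the two
p-value thresholds are strict inequalities, "at least 10" is inclusive.  By
default a non-qualifying SNP terminates a run regardless of distance
(contiguity over the tested panel); ``bridge=True`` instead skips
non-qualifying SNPs and chains qualifying ones by distance alone, for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockCriteria",
    "Block",
    "Candidate",
    "CandidateSet",
    "find_blocks",
    "select_index_snps",
    "candidates_from_blocks",
    "merge_rounds",
]


@dataclass(frozen=True)
class BlockCriteria:
    min_snps: int = 10
    max_gap_bp: int = 30_000
    p_block: float = 0.005
    p_index: float = 1e-4

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be > 0")
        if not (0.0 < self.p_index <= self.p_block < 1.0):
            raise ValueError("need 0 < p_index <= p_block < 1")


@dataclass(frozen=True)
class Block:
    """A maximal qualifying run of SNPs and its selected index SNPs."""

    chrom: str
    start_pos: int
    end_pos: int
    member_snps: tuple[tuple[str, int, float], ...]  # (snp_id, pos, p)
    index_snps: tuple[tuple[str, int, float, int], ...] = ()  # + rank
    no_index_flag: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_snps)


@dataclass(frozen=True)
class Candidate:
    snp_id: str
    rounds_found: frozenset[str]
    best_p_per_round: Mapping[str, float]
    chrom: str = ""
    pos: int = 0


@dataclass
class CandidateSet:
    disease: str
    candidates: dict[str, Candidate]

    def __len__(self) -> int:
        return len(self.candidates)


def _as_track(track) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalise a track to (chrom, pos, snp_id, p) arrays.

    Accepts a DataFrame with columns chrom/pos/snp_id/p_value (snp_id
    optional) or a sequence of (chrom, pos, p) / (chrom, pos, snp_id, p)
    tuples.
    """
    if isinstance(track, pd.DataFrame):
        chrom = track["chrom"].astype(str).to_numpy()
        pos = track["pos"].to_numpy(dtype=np.int64)
        p = track["p_value"].to_numpy(dtype=float)
        if "snp_id" in track.columns:
            snp = track["snp_id"].astype(str).to_numpy()
        else:
            snp = np.array([f"snp_{i}" for i in range(len(track))])
        return chrom, pos, snp, p
    rows = list(track)
    if rows and len(rows[0]) == 3:
        chrom = np.array([str(r[0]) for r in rows])
        pos = np.array([int(r[1]) for r in rows], dtype=np.int64)
        snp = np.array([f"snp_{i}" for i in range(len(rows))])
        p = np.array([float(r[2]) for r in rows])
    else:
        chrom = np.array([str(r[0]) for r in rows])
        pos = np.array([int(r[1]) for r in rows], dtype=np.int64)
        snp = np.array([str(r[2]) for r in rows])
        p = np.array([float(r[3]) for r in rows])
    return chrom, pos, snp, p


def _check_track(chrom: np.ndarray, pos: np.ndarray, p: np.ndarray) -> None:
    if len(chrom) == 0:
        return
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    seen: set[str] = set()
    prev_chrom: str | None = None
    for i in range(len(chrom)):
        c = chrom[i]
        if c != prev_chrom:
            if c in seen:
                raise ValueError(
                    f"track not sorted: chromosome {c!r} appears in two runs"
                )
            seen.add(c)
            prev_chrom = c
        elif pos[i] <= pos[i - 1]:
            if pos[i] == pos[i - 1]:
                raise ValueError(f"duplicate position {c}:{pos[i]}")
            raise ValueError(
                f"track not sorted by position at {c}:{pos[i]} (no silent sorting)"
            )


def find_blocks(track, criteria: BlockCriteria, *, bridge: bool = False) -> list[Block]:
    """Exactly the maximal qualifying runs on a sorted p-value track.

    The track must be sorted by (chrom, pos) with strictly increasing
    positions per chromosome; unsorted or duplicated input raises.
    """
    chrom, pos, snp, p = _as_track(track)
    _check_track(chrom, pos, p)
    blocks: list[Block] = []
    # iterate chromosome segments
    start = 0
    n = len(chrom)
    while start < n:
        end = start
        while end < n and chrom[end] == chrom[start]:
            end += 1
        blocks.extend(
            _blocks_in_segment(
                chrom[start], pos[start:end], snp[start:end], p[start:end], criteria, bridge
            )
        )
        start = end
    blocks.sort(key=lambda b: (_chrom_sort_key(b.chrom), b.start_pos))
    return blocks


def _chrom_sort_key(c: str):
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def _blocks_in_segment(
    chrom: str,
    pos: np.ndarray,
    snp: np.ndarray,
    p: np.ndarray,
    crit: BlockCriteria,
    bridge: bool,
) -> list[Block]:
    qi = np.flatnonzero(p < crit.p_block)
    if len(qi) == 0:
        return []
    gap_break = (pos[qi[1:]] - pos[qi[:-1]]) >= crit.max_gap_bp
    if bridge:
        brk = gap_break
    else:
        brk = (np.diff(qi) != 1) | gap_break
    out: list[Block] = []
    run_start = 0
    bounds = list(np.flatnonzero(brk) + 1) + [len(qi)]
    for b in bounds:
        run = qi[run_start:b]
        run_start = b
        if len(run) >= crit.min_snps:
            members = tuple(
                (str(snp[i]), int(pos[i]), float(p[i])) for i in run
            )
            out.append(
                Block(
                    chrom=str(chrom),
                    start_pos=int(pos[run[0]]),
                    end_pos=int(pos[run[-1]]),
                    member_snps=members,
                )
            )
    return out


def select_index_snps(
    blocks: Sequence[Block],
    criteria: BlockCriteria,
    *,
    inclusive: bool = False,
    max_per_block: int | None = None,
) -> list[Block]:
    """Annotate each block with its index SNPs (members below ``p_index``),
    ranked by ascending p-value.

    Blocks with no sub-threshold member are retained with an empty index set
    and flagged.  ``inclusive`` switches the index threshold to <=;
    ``max_per_block`` truncates the ranked list.
    """
    out: list[Block] = []
    for block in blocks:
        if inclusive:
            hits = [m for m in block.member_snps if m[2] <= criteria.p_index]
        else:
            hits = [m for m in block.member_snps if m[2] < criteria.p_index]
        hits.sort(key=lambda m: (m[2], m[1]))
        if max_per_block is not None:
            hits = hits[:max_per_block]
        index = tuple(
            (sid, bp, pv, rank) for rank, (sid, bp, pv) in enumerate(hits, start=1)
        )
        out.append(replace(block, index_snps=index, no_index_flag=len(index) == 0))
    return out


def candidates_from_blocks(
    disease: str, round_id: str, blocks: Sequence[Block]
) -> CandidateSet:
    """Collect the index SNPs of one scan round into a candidate set."""
    cands: dict[str, Candidate] = {}
    for block in blocks:
        for sid, bp, pv, _rank in block.index_snps:
            prev = cands.get(sid)
            if prev is None or pv < prev.best_p_per_round[round_id]:
                cands[sid] = Candidate(
                    snp_id=sid,
                    rounds_found=frozenset({round_id}),
                    best_p_per_round={round_id: pv},
                    chrom=block.chrom,
                    pos=bp,
                )
    return CandidateSet(disease=disease, candidates=cands)


def merge_rounds(round1: CandidateSet, round2: CandidateSet) -> CandidateSet:
    """Union of two rounds' candidates keyed by snp_id, keeping per-round
    provenance (|union| = |r1| + |r2| - |r1 & r2|)."""
    if round1.disease != round2.disease:
        raise ValueError(
            f"disease labels differ: {round1.disease!r} vs {round2.disease!r}"
        )
    merged: dict[str, Candidate] = dict(round1.candidates)
    for sid, cand in round2.candidates.items():
        if sid in merged:
            prev = merged[sid]
            best = dict(prev.best_p_per_round)
            for rnd, pv in cand.best_p_per_round.items():
                best[rnd] = min(pv, best.get(rnd, np.inf))
            merged[sid] = Candidate(
                snp_id=sid,
                rounds_found=prev.rounds_found | cand.rounds_found,
                best_p_per_round=best,
                chrom=prev.chrom or cand.chrom,
                pos=prev.pos or cand.pos,
            )
        else:
            merged[sid] = cand
    return CandidateSet(disease=round1.disease, candidates=merged)
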