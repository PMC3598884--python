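"""Antigen scanning: sliding-nonamer scoring, 1–100 normalization,
binder calls and the epitope ranking-percentage metric.

A protein of length L yields exactly L−8 overlapping nonamer windows.
Each window's raw PWM score is mapped linearly onto [1, 100] using the
matrix's theoretical score bounds, so 100 is the best nonamer the matrix
can ever score and 1 the worst; a normalized score ≥ 60 is called a
binder by default.  The ranking percentage of a known epitope — the rank
of its best window among all windows of the source protein, as a
percentage — is the metric used to judge immunodominant-epitope
retrieval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .pwm import PWM

DEFAULT_CUTOFF = 60.0


@dataclass(frozen=True)
class ScoredPeptide:
    """One nonamer window with raw and normalized scores."""

    nonamer: str
    offset: int  # 0-based; window covers [offset, offset+9)
    raw: float
    normalized: float
    binder: bool


@dataclass(frozen=True)
class RankingResult:
    """Ranking of a known epitope among all nonamer windows of its
    source protein (competition ranking; rank 1 = top score)."""

    epitope: str
    protein_id: str
    rank: int
    total: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.rank / self.total


def scan_protein(
    protein: str,
    pwm: PWM,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ScoredPeptide]:
    """Score every nonamer window of a protein.

    Returns L−8 windows in sequence order.  If the PWM is degenerate
    (s_min = s_max, e.g. all-zero weights) every normalized score is the
    midpoint 50.5 and a warning is emitted.
    """
    protein = protein.upper()
    if len(protein) < 9:
        raise ValueError(f"protein of length {len(protein)} has no nonamer window")
    if pwm.s_max <= pwm.s_min:
        warnings.warn(
            "degenerate PWM (s_min = s_max): all normalized scores are 50.5",
            stacklevel=2,
        )
    out = []
    for off in range(len(protein) - 8):
        window = protein[off : off + 9]
        raw = pwm.score(window)
        norm = pwm.normalized(raw)
        out.append(
            ScoredPeptide(
                nonamer=window,
                offset=off,
                raw=raw,
                normalized=norm,
                binder=norm >= cutoff,
            )
        )
    return out


def call_binders(
    scored: Sequence[ScoredPeptide], cutoff: float = DEFAULT_CUTOFF
) -> list[ScoredPeptide]:
    """Windows at or above the cutoff, best first (ties by offset)."""
    hits = [s for s in scored if s.normalized >= cutoff]
    return sorted(hits, key=lambda s: (-s.normalized, s.offset))


def _occurrences(protein: str, epitope: str) -> list[int]:
    starts, i = [], protein.find(epitope)
    while i != -1:
        starts.append(i)
        i = protein.find(epitope, i + 1)
    return starts


def rank_epitope(
    protein: str,
    epitope: str,
    pwm: PWM,
    protein_id: str = "",
) -> RankingResult:
    """Rank a known epitope's best nonamer window within its protein.

    All L−8 windows are scored and sorted descending; the epitope's rank
    is the best competition rank among windows fully contained in an
    occurrence of the epitope (tied scores share the best tied rank, and
    every occurrence of a repeated epitope counts).  Epitopes must be
    9–13 residues and occur in the protein.
    """
    protein, epitope = protein.upper(), epitope.upper()
    if not 9 <= len(epitope) <= 13:
        raise ValueError(
            f"epitope length must be 9–13 residues, got {len(epitope)}"
        )
    occ = _occurrences(protein, epitope)
    if not occ:
        raise ValueError(f"epitope {epitope!r} does not occur in the protein")
    scored = scan_protein(protein, pwm, cutoff=float("inf"))
    raws = np.array([s.raw for s in scored])

    inside = [
        s
        for s in scored
        if any(start <= s.offset and s.offset + 9 <= start + len(epitope) for start in occ)
    ]
    best_raw = max(s.raw for s in inside)
    rank = int(np.sum(raws > best_raw)) + 1  # competition rank of the tied best
    return RankingResult(epitope=epitope, protein_id=protein_id, rank=rank, total=len(scored))


def hits_to_tsv(
    hits: Sequence[ScoredPeptide],
    path: Union[str, Path],
    protein_id: str = "",
) -> None:
    """Write scored windows (protein_id, offset, nonamer, raw,
    normalized, binder), normalized-descending."""
    rows = [
        {
            "protein_id": protein_id,
            "offset": s.offset,
            "nonamer": s.nonamer,
            "raw": s.raw,
            "normalized": s.normalized,
            "binder": s.binder,
        }
        for s in sorted(hits, key=lambda s: (-s.normalized, s.offset))
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "offset", "nonamer", "raw", "normalized", "binder"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
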