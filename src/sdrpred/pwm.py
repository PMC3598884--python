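"""Per-query position-weight matrices via SDR-based data transfer.

For a query allotype, each pocket's peptide preference is estimated from
the binding cores of every stored allotype whose SDR string at that
pocket is BLOSUM62-similar to the query's (the query's own cores are
pooled too when present).  Residue frequencies at the pocket's anchored
nonamer position are smoothed with pseudocounts,

    f_adj(a) = (count_a + n/20) / (2n)  =  0.5·f_raw(a) + 0.5·(1/20),

and converted to log-odds weights w(a) = log(f_adj(a) / p(a)) against a
background composition p (uniform 1/20 by default).  A nonamer's raw
score is the sum of its anchored-residue weights; theoretical bounds
s_min/s_max (sum of per-row minima/maxima) support the downstream 1–100
normalization, which is invariant to the logarithm base chosen here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binding_db import BindingCoreStore, CoreRecord
from .hla import (
    AA_INDEX,
    AMINO_ACIDS,
    HLAAllotype,
    SDRConfiguration,
    SDRProfile,
    extract_sdr_profile,
    sdr_similar,
)

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


class EmptyPoolError(ValueError):
    """Raised in strict mode when no stored allotype matches a pocket."""


@dataclass(frozen=True)
class FrequencyColumn:
    """Residue frequencies at one anchored nonamer position.

    ``f_adj`` is the pseudocounted estimate; it always sums to one and is
    bounded below by 1/40, so log-odds weights are always finite.
    """

    pocket: str
    position: int  # 1-based nonamer position
    n: int
    f_raw: np.ndarray
    f_adj: np.ndarray


@dataclass(frozen=True)
class PWMRow:
    label: str
    anchor: int  # 1-based nonamer position this row scores
    weights: np.ndarray  # 20 log-odds values, AMINO_ACIDS order
    n_pool: int
    contributors: tuple[str, ...]


@dataclass(frozen=True)
class PWM:
    """Log-odds weight matrix for one query allotype.

    Default shape is one row per pocket (five rows anchored at nonamer
    positions 1, 4, 6, 7, 9; the other four positions contribute zero).
    The ``nonamer`` build mode adds rows for positions 2, 3, 5 and 8.
    """

    allele: str
    rows: tuple[PWMRow, ...]
    background: np.ndarray

    @property
    def s_min(self) -> float:
        return float(sum(row.weights.min() for row in self.rows)) if self.rows else 0.0

    @property
    def s_max(self) -> float:
        return float(sum(row.weights.max() for row in self.rows)) if self.rows else 0.0

    def score(self, nonamer: str) -> float:
        """Raw additive score of a 9-mer; residue X contributes zero."""
        if len(nonamer) != 9:
            raise ValueError(f"expected a nonamer, got {nonamer!r}")
        total = 0.0
        for row in self.rows:
            aa = nonamer[row.anchor - 1]
            idx = AA_INDEX.get(aa)
            if idx is None:
                if aa != "X":
                    raise ValueError(f"non-standard residue {aa!r} in {nonamer!r}")
                warnings.warn(
                    f"ambiguous residue X at nonamer position {row.anchor}; "
                    "scored as neutral (0)",
                    stacklevel=2,
                )
                continue
            total += float(row.weights[idx])
        return total

    def normalized(self, raw: float) -> float:
        """Map a raw score linearly onto [1, 100] using the theoretical
        bounds; a degenerate matrix (s_min = s_max) maps everything to
        the midpoint 50.5."""
        lo, hi = self.s_min, self.s_max
        if hi <= lo:
            return 50.5
        return 1.0 + 99.0 * (raw - lo) / (hi - lo)

    def extreme_nonamers(self) -> tuple[str, str]:
        """The (argmin, argmax) nonamers: worst/best residue at each
        anchored position, alanine at unanchored positions."""
        worst = list("AAAAAAAAA")
        best = list("AAAAAAAAA")
        for row in self.rows:
            worst[row.anchor - 1] = AMINO_ACIDS[int(np.argmin(row.weights))]
            best[row.anchor - 1] = AMINO_ACIDS[int(np.argmax(row.weights))]
        return "".join(worst), "".join(best)

    # -- serialization ---------------------------------------------------

    def save(self, tsv_path: Union[str, Path]) -> None:
        tsv_path = Path(tsv_path)
        rows = []
        for row in self.rows:
            d = {"row": row.label, "nonamer_position": row.anchor}
            d.update({aa: row.weights[i] for i, aa in enumerate(AMINO_ACIDS)})
            rows.append(d)
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "allele": self.allele,
            "background": list(self.background),
            "s_min": self.s_min,
            "s_max": self.s_max,
            "pools": {
                row.label: {"n": row.n_pool, "contributors": list(row.contributors)}
                for row in self.rows
            },
        }
        tsv_path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, tsv_path: Union[str, Path]) -> "PWM":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t")
        sidecar = json.loads(tsv_path.with_suffix(".json").read_text())
        rows = []
        for rec in df.itertuples(index=False):
            pool = sidecar["pools"].get(rec.row, {"n": 0, "contributors": []})
            rows.append(
                PWMRow(
                    label=rec.row,
                    anchor=int(rec.nonamer_position),
                    weights=np.array([getattr(rec, aa) for aa in AMINO_ACIDS]),
                    n_pool=int(pool["n"]),
                    contributors=tuple(pool["contributors"]),
                )
            )
        return cls(
            allele=sidecar["allele"],
            rows=tuple(rows),
            background=np.array(sidecar["background"]),
        )


# ---------------------------------------------------------------------------
# pool retrieval and estimation
# ---------------------------------------------------------------------------

def retrieve_pool(
    query_profile: SDRProfile,
    pocket: str,
    store: BindingCoreStore,
    similarity_mode: str = "all_positive",
) -> tuple[list[CoreRecord], tuple[str, ...]]:
    """Collect cores from every stored allotype whose SDR string at this
    pocket is similar to the query's (the query itself qualifies when it
    is in the store).  Returns the pooled cores and the contributing
    allotype names."""
    query_sdr = query_profile.sdr_string(pocket)
    pool: list[CoreRecord] = []
    contributors: list[str] = []
    for allele in sorted(store.cores):
        profile = store.profiles[allele]
        if sdr_similar(query_sdr, profile.sdr_string(pocket), mode=similarity_mode):
            recs = store.cores[allele]
            if recs:
                pool.extend(recs)
                contributors.append(allele)
    return pool, tuple(contributors)


def estimate_frequencies(
    cores: Sequence[CoreRecord], peptide_position: int, pocket: str = ""
) -> FrequencyColumn:
    """Pseudocounted residue frequencies at a 1-based nonamer position."""
    n = len(cores)
    if n == 0:
        raise ValueError("cannot estimate frequencies from an empty pool")
    if not 1 <= peptide_position <= 9:
        raise ValueError(f"nonamer position must be 1..9, got {peptide_position}")
    counts = np.zeros(20)
    for rec in cores:
        counts[AA_INDEX[rec.core[peptide_position - 1]]] += 1.0
    f_raw = counts / n
    f_adj = (counts + n / 20.0) / (2.0 * n)
    return FrequencyColumn(pocket=pocket, position=peptide_position, n=n, f_raw=f_raw, f_adj=f_adj)


def compute_weights(
    column: FrequencyColumn,
    background: Optional[np.ndarray] = None,
    log_base: Optional[float] = None,
) -> np.ndarray:
    """Log-odds weights w(a) = log(f_adj(a)/p(a)); natural log unless a
    base is given (the choice cancels after 1–100 normalization)."""
    p = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if np.any(p <= 0):
        raise ValueError("background frequencies must be strictly positive")
    w = np.log(column.f_adj / p)
    if log_base is not None:
        w = w / math.log(log_base)
    return w


def build_pwm(
    query: Union[HLAAllotype, SDRProfile],
    store: BindingCoreStore,
    sdr_config: SDRConfiguration,
    background: Optional[np.ndarray] = None,
    mode: str = "pocket",
    strict: bool = False,
    log_base: Optional[float] = None,
    similarity_mode: str = "all_positive",
) -> PWM:
    """Assemble the query-specific PWM by pooling per pocket.

    Each pocket pools independently (different pockets may draw on
    different allotype subsets).  A pocket whose pool is empty falls back
    to a zero-weight row with a warning — or raises
    :class:`EmptyPoolError` in strict mode.  ``mode="nonamer"`` adds rows
    for the four unanchored positions (2, 3, 5, 8), estimated from the P1
    pool, for the nine-row reading of the scoring model.
    """
    profile = (
        query
        if isinstance(query, SDRProfile)
        else extract_sdr_profile(query, sdr_config)
    )
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)

    rows: list[PWMRow] = []
    pools: dict[str, tuple[list[CoreRecord], tuple[str, ...]]] = {}
    for pocket in sdr_config.pockets:
        pool, contributors = retrieve_pool(profile, pocket, store, similarity_mode)
        pools[pocket] = (pool, contributors)
        anchor = sdr_config.peptide_anchor[pocket]
        if not pool:
            if strict:
                raise EmptyPoolError(
                    f"{profile.allotype}: no stored allotype shares similar "
                    f"SDRs at pocket {pocket}"
                )
            warnings.warn(
                f"{profile.allotype}: empty pool at pocket {pocket}; "
                "row falls back to zero weights",
                stacklevel=2,
            )
            rows.append(PWMRow(pocket, anchor, np.zeros(20), 0, ()))
            continue
        column = estimate_frequencies(pool, anchor, pocket)
        rows.append(
            PWMRow(pocket, anchor, compute_weights(column, bg, log_base), len(pool), contributors)
        )

    if mode == "nonamer":
        anchored = {row.anchor for row in rows}
        p1_pool, p1_contrib = pools[sdr_config.pockets[0]]
        for pos in range(1, 10):
            if pos in anchored:
                continue
            label = f"POS{pos}"
            if not p1_pool:
                rows.append(PWMRow(label, pos, np.zeros(20), 0, ()))
                continue
            column = estimate_frequencies(p1_pool, pos, label)
            rows.append(
                PWMRow(label, pos, compute_weights(column, bg, log_base), len(p1_pool), p1_contrib)
            )
    elif mode != "pocket":
        raise ValueError(f"unknown PWM mode {mode!r}")

    rows.sort(key=lambda r: (r.anchor, r.label))
    return PWM(allele=profile.allotype, rows=tuple(rows), background=bg)
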