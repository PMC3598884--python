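"""High-affinity binding-core database.

MHC class II ligands are 9–22 residues long but only a nonameric *core*
occupies the groove, so variable-length ligands must be aligned to a
common 9-mer register before position-specific statistics make sense.
This module filters raw binding records down to high-affinity ligands
(IC50 ≤ 50 nM by default), aligns them with a Gibbs sampler, and indexes
the resulting cores by allotype together with each allotype's SDR profile.

The kinetics helpers document why the affinity threshold targets
immunodominance: dominant epitopes show pMHC half-lives ≥ 100 h, and with
diffusion-limited on-rates (1e4–1e5 M⁻¹s⁻¹) that half-life corresponds to
sub-nanomolar dissociation constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hla import AA_INDEX, AMINO_ACIDS, HLAAllotype, SDRConfiguration, SDRProfile, profiles_for

#: ln 2 to the three figures conventionally used in half-life conversions.
LN2 = 0.693

ASSAYS = ("biochemical", "whole_cell", "unknown")


@dataclass(frozen=True)
class BindingRecord:
    """One ligand measurement: allele, peptide, affinity, assay type."""

    allele: str
    peptide: str
    ic50_nM: Optional[float] = None
    assay: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        object.__setattr__(self, "peptide", self.peptide.upper())
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50_nM}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay type {self.assay!r}")


@dataclass(frozen=True)
class CoreRecord:
    """A nonameric binding core located within its source ligand."""

    allele: str
    core: str
    peptide: str
    offset: int

    def __post_init__(self) -> None:
        if len(self.core) != 9:
            raise ValueError(f"core must be 9 residues, got {self.core!r}")
        if self.peptide[self.offset : self.offset + 9] != self.core:
            raise ValueError(
                f"core {self.core!r} not at offset {self.offset} of {self.peptide!r}"
            )


# ---------------------------------------------------------------------------
# record filtering
# ---------------------------------------------------------------------------

def read_records_tsv(path: Union[str, Path]) -> list[BindingRecord]:
    """Read a binding-record table (columns: allele, peptide, ic50_nM,
    assay, source; ``#`` comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        ic50 = float(row.ic50_nM) if str(row.ic50_nM).strip() else None
        records.append(
            BindingRecord(
                allele=row.allele,
                peptide=row.peptide,
                ic50_nM=ic50,
                assay=row.assay or "unknown",
                source=getattr(row, "source", ""),
            )
        )
    return records


def write_records_tsv(records: Sequence[BindingRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "allele": r.allele,
                "peptide": r.peptide,
                "ic50_nM": "" if r.ic50_nM is None else r.ic50_nM,
                "assay": r.assay,
                "source": r.source,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _nonstandard_or_ala_rich(peptide: str) -> bool:
    if any(c not in AMINO_ACIDS for c in peptide):
        return True
    return peptide.count("A") / len(peptide) > 0.5


def filter_records(
    records: Sequence[BindingRecord],
    affinity_cutoff_nM: float = 50.0,
) -> tuple[list[BindingRecord], dict[str, int]]:
    """Apply the ligand-selection filters in order and count rejections.

    (i) peptides shorter than 9 residues; (ii) peptides with any letter
    outside the 20 standard amino acids, or more than 50% alanine;
    (iii) records measured only by whole-cell assays (a whole-cell record
    survives if a biochemical measurement exists for the same
    allele/peptide pair); (iv) records with no IC50 or IC50 above the
    cutoff (boundary inclusive: IC50 = cutoff is retained).

    Returns the survivors plus a per-filter rejection count; counts
    partition the input (``retained + Σ rejections == len(records)``).
    """
    counts = {"short": 0, "nonstandard_or_ala": 0, "whole_cell_only": 0, "affinity": 0}

    stage1 = []
    for r in records:
        if len(r.peptide) < 9:
            counts["short"] += 1
        else:
            stage1.append(r)

    stage2 = []
    for r in stage1:
        if _nonstandard_or_ala_rich(r.peptide):
            counts["nonstandard_or_ala"] += 1
        else:
            stage2.append(r)

    biochem_pairs = {
        (r.allele, r.peptide) for r in stage2 if r.assay == "biochemical"
    }
    stage3 = []
    for r in stage2:
        if r.assay == "whole_cell" and (r.allele, r.peptide) not in biochem_pairs:
            counts["whole_cell_only"] += 1
        else:
            stage3.append(r)

    kept = []
    for r in stage3:
        if r.ic50_nM is None or r.ic50_nM > affinity_cutoff_nM:
            counts["affinity"] += 1
        else:
            kept.append(r)

    counts["retained"] = len(kept)
    return kept, counts


# ---------------------------------------------------------------------------
# Gibbs nonamer-core alignment
# ---------------------------------------------------------------------------

def _encode(peptides: Sequence[str]) -> list[np.ndarray]:
    out = []
    for p in peptides:
        try:
            out.append(np.array([AA_INDEX[c] for c in p], dtype=np.int64))
        except KeyError as exc:
            raise ValueError(f"non-standard residue {exc} in peptide {p!r}") from exc
    return out


def _count_matrix(encoded: Sequence[np.ndarray], offsets: np.ndarray, core_len: int) -> np.ndarray:
    counts = np.zeros((20, core_len), dtype=np.float64)
    cols = np.arange(core_len)
    for pep, off in zip(encoded, offsets):
        counts[pep[off : off + core_len], cols] += 1.0
    return counts


def _log_odds(counts: np.ndarray) -> np.ndarray:
    """Pseudocounted log-odds against a uniform background.

    Uses the same smoothing rule as the PWM engine: adjusted frequency
    ``(count + n/20) / 2n`` where n is the number of aligned cores.
    """
    n = counts.sum(axis=0)[0] if counts.size else 0.0
    n = max(float(n), 1e-12)
    f_adj = (counts + n / 20.0) / (2.0 * n)
    return np.log(f_adj / (1.0 / 20.0))


def alignment_objective(
    peptides: Sequence[str], offsets: Sequence[int], core_len: int = 9
) -> float:
    """Sum of core log-odds scores under the count matrix implied by the
    given offsets — the quantity the sampler's greedy phase maximises."""
    encoded = _encode(peptides)
    off = np.asarray(offsets, dtype=np.int64)
    return _objective(encoded, off, core_len)


def _objective(encoded, offsets, core_len) -> float:
    w = _log_odds(_count_matrix(encoded, offsets, core_len))
    cols = np.arange(core_len)
    return float(
        sum(w[pep[o : o + core_len], cols].sum() for pep, o in zip(encoded, offsets))
    )


@dataclass
class GibbsResult:
    """Alignment result: per-peptide core offsets, the final 20×L count
    matrix, and the objective trace of the closing greedy phase."""

    offsets: np.ndarray
    counts: np.ndarray
    greedy_objectives: list[float]


def gibbs_core_sampler(
    peptides: Sequence[str],
    core_len: int = 9,
    iterations: int = 100,
    restarts: int = 5,
    seed: int = 0,
) -> GibbsResult:
    """Align variable-length ligands to a common nonamer register.

    Classic leave-one-out Gibbs motif sampling: repeatedly hold one ligand
    out, score each of its windows against the pseudocounted log-odds of
    the remaining cores, and resample its offset from the Boltzmann
    distribution of window scores under a cooling temperature.  Each
    restart ends with a deterministic greedy pass that accepts only
    offset moves improving the global objective (so the objective trace is
    non-decreasing); the best restart wins.  Fully reproducible from
    ``seed``.
    """
    if len(peptides) < 2:
        raise ValueError("need at least two peptides to align")
    for p in peptides:
        if len(p) < core_len:
            raise ValueError(f"peptide {p!r} shorter than core length {core_len}")
    encoded = _encode(peptides)
    n_windows = np.array([len(p) - core_len + 1 for p in encoded])
    cols = np.arange(core_len)

    if np.all(n_windows == 1):
        # every ligand is exactly one core: nothing to sample
        offsets = np.zeros(len(encoded), dtype=np.int64)
        counts = _count_matrix(encoded, offsets, core_len)
        return GibbsResult(offsets, counts, [_objective(encoded, offsets, core_len)])

    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, list[float]]] = None
    temperatures = np.linspace(1.5, 0.2, iterations)

    for _ in range(restarts):
        offsets = np.array([rng.integers(0, nw) for nw in n_windows], dtype=np.int64)
        counts = _count_matrix(encoded, offsets, core_len)
        for temp in temperatures:
            for i, pep in enumerate(encoded):
                counts[pep[offsets[i] : offsets[i] + core_len], cols] -= 1.0
                w = _log_odds(counts)
                starts = np.arange(n_windows[i])
                scores = np.array(
                    [w[pep[s : s + core_len], cols].sum() for s in starts]
                )
                logits = scores / temp
                probs = np.exp(logits - logits.max())
                probs /= probs.sum()
                offsets[i] = rng.choice(starts, p=probs)
                counts[pep[offsets[i] : offsets[i] + core_len], cols] += 1.0

        trace = [_objective(encoded, offsets, core_len)]
        improved = True
        while improved:
            improved = False
            for i, pep in enumerate(encoded):
                current = trace[-1]
                best_move, best_obj = offsets[i], current
                for s in range(n_windows[i]):
                    if s == offsets[i]:
                        continue
                    trial = offsets.copy()
                    trial[i] = s
                    obj = _objective(encoded, trial, core_len)
                    if obj > best_obj or (obj == best_obj and s < best_move):
                        best_move, best_obj = s, obj
                if best_obj > current:
                    offsets[i] = best_move
                    trace.append(best_obj)
                    improved = True

        final = trace[-1]
        if best is None or final > best[0]:
            best = (final, offsets.copy(), trace)

    assert best is not None
    _, offsets, trace = best
    return GibbsResult(offsets, _count_matrix(encoded, offsets, core_len), trace)


def identify_cores(
    peptides: Sequence[str], motif_counts: np.ndarray
) -> list[tuple[int, str]]:
    """Locate each peptide's binding core under a fixed motif.

    The core is the maximum-scoring window under the motif's pseudocounted
    log-odds; equal-scoring windows resolve to the smallest offset.
    Returns ``(offset, core)`` per peptide.
    """
    core_len = motif_counts.shape[1]
    w = _log_odds(motif_counts)
    cols = np.arange(core_len)
    out = []
    for p in peptides:
        if len(p) < core_len:
            raise ValueError(f"peptide {p!r} shorter than core length {core_len}")
        pep = _encode([p])[0]
        scores = np.array(
            [w[pep[s : s + core_len], cols].sum() for s in range(len(p) - core_len + 1)]
        )
        off = int(np.argmax(scores))  # argmax takes the first maximum
        out.append((off, p[off : off + core_len]))
    return out


# ---------------------------------------------------------------------------
# the store
# ---------------------------------------------------------------------------

@dataclass
class BindingCoreStore:
    """Allele-indexed store of nonameric high-affinity cores and SDR
    profiles, with provenance metadata (filter counts, sampler seed)."""

    cores: dict[str, list[CoreRecord]] = field(default_factory=dict)
    profiles: dict[str, SDRProfile] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele in self.cores:
            if allele not in self.profiles:
                raise ValueError(f"allele {allele} has cores but no SDR profile")
            seen = set()
            for c in self.cores[allele]:
                if (allele, c.core) in seen:
                    raise ValueError(f"duplicate core {c.core} for {allele}")
                seen.add((allele, c.core))

    @property
    def alleles(self) -> list[str]:
        return sorted(self.cores)

    @property
    def n_cores(self) -> int:
        return sum(len(v) for v in self.cores.values())

    def without_allele(self, allele: str) -> "BindingCoreStore":
        """Copy of the store with one allele's cores and profile removed
        (the leave-one-allele-out training complement)."""
        return BindingCoreStore(
            cores={a: list(v) for a, v in self.cores.items() if a != allele},
            profiles={a: p for a, p in self.profiles.items() if a != allele},
            meta={**self.meta, "excluded_allele": allele},
        )

    # -- serialization: sorted TSV + JSON, diff-able and hash-stable -----

    def save(self, directory: Union[str, Path]) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = [
            {"allele": a, "core": c.core, "source_peptide": c.peptide, "offset": c.offset}
            for a in sorted(self.cores)
            for c in sorted(self.cores[a], key=lambda c: (c.core, c.peptide, c.offset))
        ]
        pd.DataFrame(rows, columns=["allele", "core", "source_peptide", "offset"]).to_csv(
            d / "cores.tsv", sep="\t", index=False
        )
        prof_rows = []
        for a in sorted(self.profiles):
            p = self.profiles[a]
            for pocket in sorted(p.pockets):
                prof_rows.append({"allele": a, "pocket": pocket, "sdr": p.pockets[pocket]})
        pd.DataFrame(prof_rows, columns=["allele", "pocket", "sdr"]).to_csv(
            d / "sdr_profiles.tsv", sep="\t", index=False
        )
        (d / "meta.json").write_text(json.dumps(self.meta, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "BindingCoreStore":
        d = Path(directory)
        cores: dict[str, list[CoreRecord]] = {}
        df = pd.read_csv(d / "cores.tsv", sep="\t", dtype={"offset": int})
        for row in df.itertuples(index=False):
            cores.setdefault(row.allele, []).append(
                CoreRecord(row.allele, row.core, row.source_peptide, int(row.offset))
            )
        profiles: dict[str, SDRProfile] = {}
        pdf = pd.read_csv(d / "sdr_profiles.tsv", sep="\t")
        for allele, grp in pdf.groupby("allele"):
            profiles[str(allele)] = SDRProfile(
                allotype=str(allele),
                pockets={r.pocket: r.sdr for r in grp.itertuples(index=False)},
            )
        meta = json.loads((d / "meta.json").read_text())
        return cls(cores=cores, profiles=profiles, meta=meta)


def build_store(
    records: Sequence[BindingRecord],
    allotypes: Sequence[HLAAllotype],
    sdr_config: SDRConfiguration,
    affinity_cutoff_nM: float = 50.0,
    iterations: int = 100,
    restarts: int = 5,
    seed: int = 0,
    min_peptides: int = 2,
) -> BindingCoreStore:
    """Run the full database pipeline: filter → align → index.

    Per allele: apply :func:`filter_records`, align the surviving ligands
    with :func:`gibbs_core_sampler`, locate cores with
    :func:`identify_cores`, and collapse duplicate (allele, core) pairs.
    Alleles with fewer than ``min_peptides`` ligands are stored but
    flagged low-support (a single ligand contributes its offset-0 window).
    Deterministic for fixed inputs and seed.
    """
    profiles = profiles_for(allotypes, sdr_config)
    missing = sorted({r.allele for r in records} - set(profiles))
    if missing:
        raise ValueError(f"records reference alleles without sequences: {missing}")

    kept, filter_counts = filter_records(records, affinity_cutoff_nM)
    by_allele: dict[str, list[str]] = {}
    for r in kept:
        by_allele.setdefault(r.allele, []).append(r.peptide)

    cores: dict[str, list[CoreRecord]] = {}
    low_support: list[str] = []
    ss = np.random.SeedSequence(seed)
    for allele in sorted(by_allele):
        peptides = by_allele[allele]
        allele_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        if len(peptides) < min_peptides:
            low_support.append(allele)
            located = [(0, p[:9]) for p in peptides]
        else:
            result = gibbs_core_sampler(
                peptides, core_len=9, iterations=iterations,
                restarts=restarts, seed=allele_seed,
            )
            located = identify_cores(peptides, result.counts)
        seen: set[str] = set()
        recs = []
        for pep, (off, core) in zip(peptides, located):
            if core in seen:
                continue
            seen.add(core)
            recs.append(CoreRecord(allele, core, pep, off))
        cores[allele] = recs

    return BindingCoreStore(
        cores=cores,
        profiles={a: profiles[a] for a in sorted(profiles)},
        meta={
            "affinity_cutoff_nM": affinity_cutoff_nM,
            "seed": seed,
            "iterations": iterations,
            "restarts": restarts,
            "filter_counts": filter_counts,
            "low_support": low_support,
        },
    )


def remove_redundancy(
    store: BindingCoreStore, test_epitopes: Sequence[str]
) -> tuple[BindingCoreStore, int]:
    """Strip train/test overlap before benchmarking.

    Drops every stored core that equals a test epitope, contains one, or
    is contained in one (containment is checked both ways because cores
    are 9-mers while test epitopes may be longer or shorter).
    """
    epitopes = [e.upper() for e in test_epitopes if e]
    removed = 0
    new_cores: dict[str, list[CoreRecord]] = {}
    for allele, recs in store.cores.items():
        kept = []
        for rec in recs:
            if any(e in rec.core or rec.core in e for e in epitopes):
                removed += 1
            else:
                kept.append(rec)
        new_cores[allele] = kept
    return (
        BindingCoreStore(
            cores=new_cores,
            profiles=dict(store.profiles),
            meta={**store.meta, "redundancy_removed": removed},
        ),
        removed,
    )


# ---------------------------------------------------------------------------
# pMHC kinetics
# ---------------------------------------------------------------------------

def halflife_to_koff(t_half_hours: float) -> float:
    """Dissociation rate k_off (s⁻¹) from complex half-life in hours:
    k_off = 0.693 / t½."""
    if t_half_hours <= 0:
        raise ValueError("half-life must be positive")
    return LN2 / (t_half_hours * 3600.0)


def kd_from_rates(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant K_d (molar) = k_off / k_on."""
    if k_off <= 0 or k_on <= 0:
        raise ValueError("rate constants must be positive")
    return k_off / k_on


@dataclass(frozen=True)
class KineticConstants:
    """pMHC dissociation kinetics bundle (hours / s⁻¹ / M⁻¹s⁻¹ / molar)."""

    t_half: float
    k_off: float
    k_on: float
    K_d: float

    @classmethod
    def from_halflife(cls, t_half_hours: float, k_on: float) -> "KineticConstants":
        k_off = halflife_to_koff(t_half_hours)
        return cls(t_half=t_half_hours, k_off=k_off, k_on=k_on, K_d=kd_from_rates(k_off, k_on))
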