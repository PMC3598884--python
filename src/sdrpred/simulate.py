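"""Self-contained synthetic test worlds for the SDR-transfer method.

The generative model mirrors the method's own assumptions: each pocket of
each allotype has an independent categorical preference distribution over
the 20 residues, and allotypes engineered to share BLOSUM62-similar SDRs
at a pocket share that pocket's distribution — the premise that a small
set of groove residues determines pocket chemistry.  From these ground
truths the module samples high-affinity nonamer cores, embeds them in
variable-length ligands with known core offsets (for sampler-recovery
tests), and plants consensus epitopes in random antigens (for ranking
tests).  Everything is reproducible from (design, seed).

Sharpness of the pocket preferences is a symmetric-Dirichlet
concentration knob: small values give near-deterministic anchor
preferences, emulating the strong residue preferences of high-affinity
binding data without modelling IC50 numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .binding_db import BindingRecord
from .hla import AMINO_ACIDS, HLAAllotype, SDRConfiguration, SDRProfile, extract_sdr_profile
from .pwm import PWM, PWMRow, UNIFORM_BACKGROUND

#: Residues that are pairwise BLOSUM62-negative yet self-positive; writing
#: group g's SDRs with letter g makes same-group allotypes identical and
#: different-group allotypes dissimilar at every pocket position.
DISSIMILAR_RESIDUES = "LDGWP"

BETA1_LENGTH = 90
DEFAULT_CONCENTRATION = 0.1


@dataclass(frozen=True)
class GroundTruthProfile:
    """The generative truth for one allotype: per-pocket preference
    distributions plus the SDR profile realizing the similarity design."""

    allotype: str
    pocket_dists: dict[str, np.ndarray]
    sdr_profile: SDRProfile


# -- similarity designs ------------------------------------------------------

def full_sharing(n: int, config: SDRConfiguration) -> dict[str, list[int]]:
    """Every allotype in one group at every pocket."""
    return {p: [0] * n for p in config.pockets}


def no_sharing(n: int, config: SDRConfiguration) -> dict[str, list[int]]:
    """Every allotype its own group at every pocket (≤ 5 allotypes)."""
    return {p: list(range(n)) for p in config.pockets}


def paired_sharing(n: int, config: SDRConfiguration) -> dict[str, list[int]]:
    """Consecutive pairs share all pockets; a trailing odd allotype is
    isolated.  E.g. n=5 → groups [0, 0, 1, 1, 2]."""
    return {p: [i // 2 for i in range(n)] for p in config.pockets}


def generate_panel(
    n_allotypes: int,
    similarity_graph: dict[str, Sequence[int]],
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
    sdr_config: Optional[SDRConfiguration] = None,
) -> tuple[list[HLAAllotype], list[GroundTruthProfile], SDRConfiguration]:
    """Emit β1-like sequences realizing a designed SDR-sharing graph.

    ``similarity_graph`` maps each pocket to one group id per allotype:
    allotypes in the same group at a pocket receive identical SDR
    residues there (hence BLOSUM62-similar) and share the pocket's
    ground-truth preference distribution; allotypes in different groups
    receive pairwise BLOSUM62-negative residues and independent
    distributions.  Non-SDR positions are random.  At most five groups
    per pocket are realizable; more is an infeasible design.
    """
    if n_allotypes < 2:
        raise ValueError("need at least two allotypes")
    config = sdr_config or SDRConfiguration.default()
    for pocket in config.pockets:
        groups = similarity_graph.get(pocket)
        if groups is None or len(groups) != n_allotypes:
            raise ValueError(f"similarity graph must assign every allotype a group at {pocket}")
        if max(groups) >= len(DISSIMILAR_RESIDUES):
            raise ValueError(
                f"infeasible design: pocket {pocket} needs more than "
                f"{len(DISSIMILAR_RESIDUES)} mutually dissimilar SDR groups"
            )
    # overlapping pockets with conflicting group structure cannot both be
    # realized on a shared β position
    pos_owner: dict[int, str] = {}
    for pocket in config.pockets:
        for pos in config.positions[pocket]:
            other = pos_owner.get(pos)
            if other is not None and list(similarity_graph[pocket]) != list(similarity_graph[other]):
                raise ValueError(
                    f"infeasible design: β position {pos} is shared by pockets "
                    f"{other} and {pocket} with different group assignments"
                )
            pos_owner[pos] = pocket

    rng = np.random.default_rng(seed)
    length = max(BETA1_LENGTH, config.max_position)

    # one preference distribution per (pocket, group)
    dists: dict[tuple[str, int], np.ndarray] = {}
    for pocket in config.pockets:
        for g in sorted(set(similarity_graph[pocket])):
            dists[(pocket, g)] = rng.dirichlet([concentration] * 20)

    allotypes: list[HLAAllotype] = []
    truths: list[GroundTruthProfile] = []
    for i in range(n_allotypes):
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        for pocket in config.pockets:
            g = similarity_graph[pocket][i]
            for pos in config.positions[pocket]:
                seq[pos - 1] = DISSIMILAR_RESIDUES[g]
        name = f"DRB1*{90 + i // 99:02d}:{i % 99 + 1:02d}"
        allotype = HLAAllotype(name=name, beta1_seq="".join(seq))
        allotypes.append(allotype)
        truths.append(
            GroundTruthProfile(
                allotype=name,
                pocket_dists={
                    p: dists[(p, similarity_graph[p][i])] for p in config.pockets
                },
                sdr_profile=extract_sdr_profile(allotype, config),
            )
        )
    return allotypes, truths, config


def panel_to_fasta(allotypes: Sequence[HLAAllotype], path: Union[str, Path]) -> None:
    """Write a panel as FASTA with the allele name as first header token."""
    with open(path, "w") as fh:
        for a in allotypes:
            fh.write(f">{a.name} synthetic\n{a.beta1_seq}\n")


# -- cores, ligands, records -------------------------------------------------

def sample_cores(
    profile: GroundTruthProfile,
    n: int,
    seed: int = 0,
    sdr_config: Optional[SDRConfiguration] = None,
) -> list[str]:
    """Draw n nonamer cores: anchored positions from the pocket
    distributions, unanchored positions uniform."""
    if n < 1:
        raise ValueError("need n >= 1 cores")
    config = sdr_config or SDRConfiguration.default()
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    anchor_of = {config.peptide_anchor[p]: p for p in config.pockets}
    cores = []
    for _ in range(n):
        core = [
            letters[rng.choice(20, p=profile.pocket_dists[anchor_of[pos]])]
            if pos in anchor_of
            else rng.choice(letters)
            for pos in range(1, 10)
        ]
        cores.append("".join(core))
    return cores


def embed_in_ligands(
    cores: Sequence[str],
    flank_range: tuple[int, int] = (0, 6),
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """Pad cores with uniform-random flanks; returns the ligands and the
    true core offsets (= left-flank lengths) for recovery tests."""
    lo, hi = flank_range
    if lo < 0 or hi < lo:
        raise ValueError(f"bad flank range {flank_range}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    ligands, offsets = [], []
    for core in cores:
        left = int(rng.integers(lo, hi + 1))
        right = int(rng.integers(lo, hi + 1))
        lf = "".join(rng.choice(letters, size=left))
        rf = "".join(rng.choice(letters, size=right))
        ligands.append(lf + core + rf)
        offsets.append(left)
    return ligands, offsets


def records_from_peptides(
    allele: str,
    peptides: Sequence[str],
    seed: int = 0,
    ic50_range_nM: tuple[float, float] = (1.0, 50.0),
) -> list[BindingRecord]:
    """Wrap synthetic ligands as high-affinity biochemical records so the
    database pipeline can consume them."""
    rng = np.random.default_rng(seed)
    lo, hi = ic50_range_nM
    return [
        BindingRecord(
            allele=allele,
            peptide=p,
            ic50_nM=float(rng.uniform(lo, hi)),
            assay="biochemical",
            source="synthetic",
        )
        for p in peptides
    ]


# -- antigens with planted epitopes ------------------------------------------

def truth_pwm(
    profile: GroundTruthProfile,
    sdr_config: Optional[SDRConfiguration] = None,
    background: Optional[np.ndarray] = None,
) -> PWM:
    """The infinite-data PWM of a ground-truth profile: pocket weights
    log((0.5·dist + 0.025)/p), i.e. the limit of the pseudocounted
    estimator as the core pool grows."""
    config = sdr_config or SDRConfiguration.default()
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    rows = tuple(
        PWMRow(
            label=pocket,
            anchor=config.peptide_anchor[pocket],
            weights=np.log((0.5 * profile.pocket_dists[pocket] + 0.025) / bg),
            n_pool=0,
            contributors=("ground-truth",),
        )
        for pocket in config.pockets
    )
    return PWM(allele=profile.allotype, rows=rows, background=bg)


def consensus_epitope(
    profile: GroundTruthProfile,
    sdr_config: Optional[SDRConfiguration] = None,
) -> str:
    """The profile's consensus nonamer: modal residue at each anchored
    position, serine at unanchored positions (seed-independent)."""
    config = sdr_config or SDRConfiguration.default()
    anchor_of = {config.peptide_anchor[p]: p for p in config.pockets}
    return "".join(
        AMINO_ACIDS[int(np.argmax(profile.pocket_dists[anchor_of[pos]]))]
        if pos in anchor_of
        else "S"
        for pos in range(1, 10)
    )


def plant_epitope(
    protein_len: int,
    profile: GroundTruthProfile,
    seed: int = 0,
    sdr_config: Optional[SDRConfiguration] = None,
) -> tuple[str, str, int, bool]:
    """Insert the profile's consensus epitope into a uniform-random
    antigen.

    Returns (protein, epitope, insert offset, expected_top) where
    ``expected_top`` records whether the planted window is the unique
    top-scoring window under the ground-truth PWM — occasionally a random
    background window scores as high, and ranking assertions should not
    blame the predictor for those.
    """
    if protein_len < 30:
        raise ValueError("protein_len must be at least 30")
    config = sdr_config or SDRConfiguration.default()
    rng = np.random.default_rng(seed)
    epitope = consensus_epitope(profile, config)
    backbone = rng.choice(list(AMINO_ACIDS), size=protein_len)
    insert_at = int(rng.integers(0, protein_len - 9 + 1))
    backbone[insert_at : insert_at + 9] = list(epitope)
    protein = "".join(backbone)

    pwm = truth_pwm(profile, config)
    scores = [pwm.score(protein[i : i + 9]) for i in range(len(protein) - 8)]
    planted = scores[insert_at]
    expected_top = all(
        s < planted for i, s in enumerate(scores) if i != insert_at
    )
    return protein, epitope, insert_at, expected_top
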