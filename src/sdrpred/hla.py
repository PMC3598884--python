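"""HLA-DR allotype model: allele nomenclature, β1-domain sequences and
specificity-determining residues (SDRs).

An *allotype* is the protein variant encoded by one HLA allele.  Nearly all
DR polymorphism is confined to the β1 domain, which forms the polymorphic
half of the peptide-binding groove.  The groove presents five pockets
(P1, P4, P6, P7, P9), each accommodating one anchored residue of the
nonameric binding core.  A small set of polymorphic groove positions — the
SDRs — determines which peptides an allotype binds; reading those residues
off the β1 sequence gives a transferable key: two allotypes with similar
SDRs at a pocket are assumed to share that pocket's peptide preference.

The SDR position map is configuration, not code: every downstream module
reads pocket → β-chain positions from an :class:`SDRConfiguration`.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: DR β-chain loci handled by the method.  DQ/DP groove specificity is
#: governed by both chains and far less binding data exists, so those loci
#: are rejected rather than predicted badly.
VALID_LOCI = frozenset({"DRB1", "DRB3", "DRB4", "DRB5"})


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be parsed or is out of scope."""


class SDRConfigError(ValueError):
    """Raised for an invalid SDR pocket configuration."""


_ALLELE_RE = re.compile(
    r"^(?:HLA[-:])?(?P<locus>[A-Z]+\d*)\*(?P<fields>[\d:]+)(?P<expr>[NLSCAQ]?)$"
)


def parse_allele_name(raw: str) -> str:
    """Normalize an HLA-DR allele name to the two-field ``LOCUS*GG:PP`` form.

    Accepts colon-delimited names with an optional ``HLA-`` prefix and
    higher-field suffixes (``HLA-DRB1*01:01:01`` → ``DRB1*01:01``) as well
    as legacy four-digit names (``DRB1*0401`` → ``DRB1*04:01``).

    Raises
    ------
    AlleleParseError
        If the string is unparseable, or the locus is not one of
        DRB1/DRB3/DRB4/DRB5 (DQ and DP are out of scope).
    """
    if not raw or not raw.strip():
        raise AlleleParseError("empty allele name")
    token = raw.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"unparseable allele name: {token!r}")
    locus = m.group("locus")
    if locus not in VALID_LOCI:
        raise AlleleParseError(
            f"locus {locus!r} in {token!r} is not supported: only DR β-chain "
            f"loci ({', '.join(sorted(VALID_LOCI))}) are in scope"
        )
    fields = m.group("fields")
    if ":" in fields:
        parts = [p for p in fields.split(":") if p]
        if len(parts) < 2:
            raise AlleleParseError(f"allele {token!r} has fewer than two fields")
        group, protein = parts[0], parts[1]
    else:
        # legacy concatenated-digit form: first two digits are the allele
        # group, the remainder the protein number (DRB1*0101, DRB1*1454)
        if len(fields) < 4:
            raise AlleleParseError(
                f"legacy allele {token!r} needs at least four digits"
            )
        group, protein = fields[:2], fields[2:]
    return f"{locus}*{int(group):02d}:{int(protein):02d}"


@dataclass(frozen=True)
class SDRConfiguration:
    """Pocket → SDR position map for the DR β1 domain.

    Parameters
    ----------
    pockets
        Ordered pocket labels, canonically ``("P1","P4","P6","P7","P9")``.
    positions
        Pocket label → strictly increasing 1-based β-chain positions
        (mature-protein numbering).  A β residue may serve two pockets.
    peptide_anchor
        Pocket label → the 1-based nonamer position anchored in that
        pocket (P1→1, P4→4, P6→6, P7→7, P9→9).
    """

    pockets: tuple[str, ...]
    positions: dict[str, tuple[int, ...]]
    peptide_anchor: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.pockets)) != len(self.pockets):
            raise SDRConfigError("pocket labels must be unique")
        for p in self.pockets:
            pos = self.positions.get(p)
            if not pos:
                raise SDRConfigError(f"pocket {p} has no positions")
            if list(pos) != sorted(set(pos)):
                raise SDRConfigError(
                    f"pocket {p} positions must be strictly increasing"
                )
            anchor = self.peptide_anchor.get(p)
            if anchor is None or not 1 <= anchor <= 9:
                raise SDRConfigError(
                    f"pocket {p} needs a peptide anchor in 1..9, got {anchor}"
                )

    @property
    def total_positions(self) -> int:
        """Number of distinct β-chain SDR positions across all pockets."""
        return len({p for pos in self.positions.values() for p in pos})

    @property
    def max_position(self) -> int:
        return max(p for pos in self.positions.values() for p in pos)

    @classmethod
    def default(cls) -> "SDRConfiguration":
        """The shipped 15-position DRB1-numbered pocket map.

        Drawn from published DR pocket-contact residues (TEPITOPE-style
        pocket definitions over β9, 11, 13, 28, 30, 37, 57, 61, 67, 70,
        71, 74, 78, 85, 86).  This is a documented stand-in map: the
        machinery is independent of the particular position list, and the
        whole map can be replaced via :meth:`from_json`.
        """
        return cls(
            pockets=("P1", "P4", "P6", "P7", "P9"),
            positions={
                "P1": (85, 86),
                "P4": (13, 70, 71, 74, 78),
                "P6": (11, 30),
                "P7": (28, 61, 67),
                "P9": (9, 37, 57),
            },
            peptide_anchor={"P1": 1, "P4": 4, "P6": 6, "P7": 7, "P9": 9},
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SDRConfiguration":
        data = json.loads(Path(path).read_text())
        try:
            return cls(
                pockets=tuple(data["pockets"]),
                positions={k: tuple(v) for k, v in data["positions"].items()},
                peptide_anchor={k: int(v) for k, v in data["peptide_anchor"].items()},
            )
        except KeyError as exc:  # pragma: no cover - schema message
            raise SDRConfigError(f"SDR config missing key {exc}") from exc

    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            "pockets": list(self.pockets),
            "positions": {k: list(v) for k, v in self.positions.items()},
            "peptide_anchor": dict(self.peptide_anchor),
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


@dataclass(frozen=True)
class HLAAllotype:
    """A named DR allotype with its mature β1-domain sequence.

    ``beta1_seq`` uses 1-based mature-protein numbering (position 9 of the
    chain is ``beta1_seq[8]``); input is assumed pre-trimmed to the mature
    β1 domain, no signal-peptide handling is performed.
    """

    name: str
    beta1_seq: str
    locus: str = field(default="")

    def __post_init__(self) -> None:
        if not self.locus:
            object.__setattr__(self, "locus", self.name.split("*")[0])
        seq = self.beta1_seq.upper()
        object.__setattr__(self, "beta1_seq", seq)
        bad = set(seq) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"{self.name}: non-amino-acid letters in β1 sequence: {sorted(bad)}"
            )
        if "X" in seq:
            warnings.warn(
                f"{self.name}: β1 sequence contains ambiguous residues (X)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.beta1_seq)


@dataclass(frozen=True)
class SDRProfile:
    """Per-pocket SDR residue strings for one allotype — the transfer key."""

    allotype: str
    pockets: dict[str, str]

    def sdr_string(self, pocket: str) -> str:
        return self.pockets[pocket]


def _allele_from_header(description: str) -> str:
    """Pull the first parseable DR allele token from a FASTA header."""
    for token in re.split(r"[\s|]+", description):
        try:
            return parse_allele_name(token)
        except AlleleParseError:
            continue
    raise AlleleParseError(
        f"no parseable DR allele name in FASTA header: {description!r}"
    )


def load_allotypes(
    fasta: Union[str, Path], sdr_config: SDRConfiguration
) -> list[HLAAllotype]:
    """Read DR allotypes from FASTA, one per unique normalized allele name.

    Headers may be IMGT-style (``HLA:HLA00664 DRB1*01:01:01 ...``) or bare
    allele names; the first parseable DR token is used.  Duplicate names
    with identical sequences collapse to one record; conflicting sequences
    are an error, as is any sequence too short to carry the configured SDR
    positions.  Returns allotypes sorted by name.
    """
    seen: dict[str, HLAAllotype] = {}
    max_pos = sdr_config.max_position
    for rec in SeqIO.parse(str(fasta), "fasta"):
        name = _allele_from_header(rec.description)
        seq = str(rec.seq).upper()
        if len(seq) < max_pos:
            raise ValueError(
                f"{name}: β1 sequence length {len(seq)} is shorter than the "
                f"maximal configured SDR position {max_pos}"
            )
        if name in seen:
            if seen[name].beta1_seq != seq:
                raise ValueError(
                    f"duplicate allele {name} with conflicting sequences:\n"
                    f"  kept: {seen[name].beta1_seq}\n  new:  {seq}"
                )
            continue
        seen[name] = HLAAllotype(name=name, beta1_seq=seq)
    return [seen[k] for k in sorted(seen)]


def extract_sdr_profile(
    allotype: HLAAllotype,
    sdr_config: SDRConfiguration,
    strict: bool = True,
) -> SDRProfile:
    """Read the SDR residues of each pocket off the β1 sequence.

    For each pocket the SDR string is the subsequence at the configured
    1-based positions, in order.  An ``X`` at an SDR position is an error
    in strict mode; in permissive mode it is kept as a wildcard with a
    warning (``X`` never scores positively in BLOSUM62, so a wildcard
    pocket simply matches nothing).
    """
    seq = allotype.beta1_seq
    pockets: dict[str, str] = {}
    for pocket in sdr_config.pockets:
        chars = []
        for pos in sdr_config.positions[pocket]:
            if pos > len(seq):
                raise ValueError(
                    f"{allotype.name}: SDR position {pos} beyond β1 length {len(seq)}"
                )
            chars.append(seq[pos - 1])
        s = "".join(chars)
        if "X" in s:
            if strict:
                raise ValueError(
                    f"{allotype.name}: ambiguous residue X at an SDR position "
                    f"of pocket {pocket}"
                )
            warnings.warn(
                f"{allotype.name}: X at an SDR position of pocket {pocket}; "
                "treated as a wildcard that matches no allotype",
                stacklevel=2,
            )
        pockets[pocket] = s
    return SDRProfile(allotype=allotype.name, pockets=pockets)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load(name)


def sdr_similar(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    mode: str = "all_positive",
) -> bool:
    """Decide whether two equal-length SDR strings are interchangeable.

    Default rule: every aligned residue pair must have a strictly positive
    substitution score (a zero score counts as *not* similar).  The
    alternative ``mode="sum_positive"`` requires only the summed score to
    be positive.  Symmetric in its arguments.
    """
    if len(a) != len(b):
        raise ValueError(f"SDR length mismatch: {a!r} vs {b!r}")
    mat = _load_matrix(matrix)

    def score(x: str, y: str) -> float:
        try:
            return float(mat[x][y])
        except (KeyError, IndexError):
            return float("-inf")  # wildcards / unknowns never match

    if mode == "all_positive":
        return all(score(x, y) > 0 for x, y in zip(a, b))
    if mode == "sum_positive":
        return sum(score(x, y) for x, y in zip(a, b)) > 0
    raise ValueError(f"unknown similarity mode {mode!r}")


def profiles_for(
    allotypes: Iterable[HLAAllotype],
    sdr_config: SDRConfiguration,
    strict: bool = True,
) -> dict[str, SDRProfile]:
    """Convenience: name → SDRProfile for a collection of allotypes."""
    return {a.name: extract_sdr_profile(a, sdr_config, strict=strict) for a in allotypes}
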