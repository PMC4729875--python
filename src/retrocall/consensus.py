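"""Retrotransposon consensus library with subfamily diagnostic positions.

The five subfamilies known to mobilise in modern humans (L1-Ta, L1 pre-Ta,
AluYa5, AluYb8, SVA_E) plus an LTR negative control are represented by one
consensus per subfamily.  Subfamilies of the same family share a backbone and
differ only at a handful of diagnostic positions, which is what subfamily
assignment keys on downstream.

The default library is a deterministic, scaled-down synthetic surrogate: the
sequences are random DNA of roughly element-like length, not real consensus
sequences.  Two structural constraints keep simulated junctions unambiguous
(see docs/methods.md): the first consensus base is never ``G`` (so untemplated
5' G additions cannot be absorbed into the element body) and the final 20
bases contain no ``A`` (so a planted poly-A tail has a sharp 5' boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import random_dna

# family -> subfamilies active in humans
DEFAULT_SUBFAMILIES = {
    "L1": ["L1-Ta", "L1-preTa"],
    "Alu": ["AluYa5", "AluYb8"],
    "SVA": ["SVA_E"],
    "LTR": ["LTR"],
}

# scaled-down element lengths (bases)
DEFAULT_LENGTHS = {"L1": 1200, "Alu": 300, "SVA": 700, "LTR": 500}

_N_DIAGNOSTIC = 8


@dataclass
class ConsensusLibrary:
    """Family -> subfamily -> consensus sequence, plus diagnostic positions.

    ``diagnostic_positions[family]`` is a sorted list of 0-based positions at
    which subfamilies of that family may differ.  ``diag_bases`` extracts the
    bases of one subfamily at those positions; reads in the simulator carry
    the same string so callers can vote on subfamily identity.
    """

    families: dict[str, dict[str, str]]
    diagnostic_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        for fam, subs in self.families.items():
            if not subs:
                raise ValueError(f"family {fam!r} has no subfamilies")
            lengths = {len(s) for s in subs.values()}
            if 0 in lengths:
                raise ValueError(f"family {fam!r} has an empty consensus")
            pos = self.diagnostic_positions.get(fam, [])
            if pos and max(pos) >= min(lengths):
                raise ValueError(
                    f"diagnostic position out of range for family {fam!r}")

    @property
    def family_names(self) -> list[str]:
        return list(self.families)

    def subfamilies(self, family: str) -> list[str]:
        return list(self.families[family])

    def sequence(self, family: str, subfamily: str) -> str:
        return self.families[family][subfamily]

    def diag_bases(self, family: str, subfamily: str) -> str:
        seq = self.sequence(family, subfamily)
        return "".join(seq[p] for p in self.diagnostic_positions.get(family, []))


def _constrain(seq: str) -> str:
    """Apply junction-disambiguation constraints to a consensus backbone."""
    if seq[0] == "G":
        seq = "C" + seq[1:]
    tail = seq[-20:].replace("A", "T")
    return seq[:-20] + tail


def default_library(seed: int = 7, lengths: dict[str, int] | None = None) -> ConsensusLibrary:
    """Build the deterministic synthetic consensus library.

    The same ``seed`` always yields byte-identical sequences; the default is a
    fixed constant so every pipeline run shares one reference library.
    """
    lengths = dict(DEFAULT_LENGTHS if lengths is None else lengths)
    rng = np.random.default_rng(seed)
    families: dict[str, dict[str, str]] = {}
    diag: dict[str, list[int]] = {}
    for fam, subs in DEFAULT_SUBFAMILIES.items():
        backbone = _constrain(random_dna(rng, lengths[fam], gc=0.45))
        positions = sorted(
            rng.choice(np.arange(25, lengths[fam] - 50), size=_N_DIAGNOSTIC,
                       replace=False).tolist())
        diag[fam] = positions
        families[fam] = {}
        for i, sub in enumerate(subs):
            seq = list(backbone)
            # each subfamily after the first gets private bases at every other
            # diagnostic position, spread along the element so truncated
            # insertions usually retain some of them
            if i > 0:
                for p in positions[::2]:
                    seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
            families[fam][sub] = "".join(seq)
    return ConsensusLibrary(families=families, diagnostic_positions=diag)
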