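"""Amino-acid composition calculus under hydrolysis chemistries.

A protein hydrolysate does not report the intact sequence's 20 residues.
Acid hydrolysis deamidates Gln to Glu and Asn to Asp, so the analyzer pools
them into the Glx and Asx channels; hydrolysis in 6 M HCl additionally
destroys Trp, while 4 N methanesulfonic acid (MSA) preserves it.  A
:class:`HydrolysisScheme` captures this as a residue-to-channel map plus
per-residue recovery factors, and every composition here is a mole fraction
("percentage of amino-acid numbers") of recovered channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from depositcomp.sequence_io import CANONICAL, ProteinRecord

logger = logging.getLogger(__name__)

#: One-letter -> three-letter channel label.
THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

#: Analyzer elution order used for hydrolysate tables and plots.
HYDROLYSATE_CHANNELS = (
    "Asx", "Thr", "Ser", "Glx", "Pro", "Gly", "Ala", "Cys", "Val",
    "Met", "Ile", "Leu", "Tyr", "Phe", "His", "Lys", "Arg", "Trp",
)

# IUPAC 2021 standard atomic weights.
_ATOM = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06, "Se": 78.971}

# Elemental composition of the residue (in-chain, i.e. free amino acid minus
# one water).  U is selenocysteine.
_RESIDUE_FORMULA = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "U": {"C": 3, "H": 5, "N": 1, "O": 1, "Se": 1},
}

WATER_MASS = 2 * _ATOM["H"] + _ATOM["O"]


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(n * _ATOM[el] for el, n in formula.items())


def residue_mass(residue: str) -> float:
    """In-chain mass of one residue (free amino acid minus one water), g/mol."""
    if residue not in _RESIDUE_FORMULA:
        raise ValueError(f"no defined mass for residue {residue!r}")
    return _formula_mass(_RESIDUE_FORMULA[residue])


def free_mass(residue: str) -> float:
    """Free amino-acid molecular weight, g/mol, from elemental composition."""
    return residue_mass(residue) + WATER_MASS


@dataclass(frozen=True)
class HydrolysisScheme:
    """Residue-to-channel map and recovery factors for one hydrolysis chemistry.

    ``intact`` is the identity map (no hydrolysis artefacts, channels are the
    20 one-letter residues).  ``hcl`` and ``msa`` pool Q/E into Glx and N/D
    into Asx; ``hcl`` sets Trp recovery to 0, ``msa`` to 1.
    """

    name: str
    channel_map: dict[str, str]
    recovery: dict[str, float]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(CANONICAL) - set(self.channel_map)
        if missing:
            raise ValueError(f"channel_map does not cover residues {sorted(missing)}")
        for r, v in self.recovery.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"recovery[{r!r}]={v} outside [0, 1]")

    def residues_for_channel(self, channel: str) -> list[str]:
        """Canonical residues mapping to *channel*, in alphabetical order."""
        return sorted(r for r in CANONICAL if self.channel_map[r] == channel)


def get_scheme(
    name: str, recovery_overrides: dict[str, float] | None = None
) -> HydrolysisScheme:
    """Build a named scheme: ``intact``, ``hcl`` or ``msa``.

    *recovery_overrides* adjusts per-residue recovery, e.g. ``{"C": 0.5}`` to
    model cysteine degradation during acid hydrolysis.
    """
    if name == "intact":
        channel_map = {r: r for r in CANONICAL}
        channels = tuple(CANONICAL)
        recovery = {r: 1.0 for r in CANONICAL}
    elif name in ("hcl", "msa"):
        channel_map = {}
        for r in CANONICAL:
            if r in "QE":
                channel_map[r] = "Glx"
            elif r in "ND":
                channel_map[r] = "Asx"
            else:
                channel_map[r] = THREE_LETTER[r]
        channels = HYDROLYSATE_CHANNELS
        recovery = {r: 1.0 for r in CANONICAL}
        if name == "hcl":
            recovery["W"] = 0.0
    else:
        raise ValueError(f"unknown hydrolysis scheme {name!r}")
    if recovery_overrides:
        bad = set(recovery_overrides) - set(CANONICAL)
        if bad:
            raise ValueError(f"recovery override for unknown residue(s) {sorted(bad)}")
        recovery = {**recovery, **recovery_overrides}
    return HydrolysisScheme(
        name=name, channel_map=channel_map, recovery=recovery, channels=channels
    )


@dataclass(frozen=True)
class CompositionVector:
    """Relative channel fractions of a protein, mixture or measured fraction.

    Fractions are non-negative, sum to 1 (within 1e-9) and are keyed by the
    active scheme's full channel set.  ``n_residues`` is the recovered residue
    count for sequence-derived vectors (absent for measured tables);
    ``raw_sum`` preserves the pre-renormalization column sum of a measured
    table.
    """

    scheme_name: str
    fractions: dict[str, float]
    n_residues: float | None = None
    raw_sum: float | None = None

    def __post_init__(self) -> None:
        total = 0.0
        for ch, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative fraction for channel {ch!r}")
            total += f
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total!r}, expected 1")

    def __getitem__(self, channel: str) -> float:
        return self.fractions[channel]

    def as_list(self, channels=None) -> list[float]:
        channels = list(self.fractions) if channels is None else channels
        return [self.fractions[ch] for ch in channels]


def residue_counts(record: ProteinRecord) -> dict[str, int]:
    """Count residues of a record.

    U (selenocysteine) counts as C.  B and Z are kept as their own keys (they
    resolve to the pooled Asx/Glx channels downstream).  X is excluded from
    counts and from the countable length, with a logged warning.
    """
    counts: dict[str, int] = {}
    n_x = 0
    for ch in record.sequence:
        if ch == "X":
            n_x += 1
            continue
        if ch == "U":
            ch = "C"
        counts[ch] = counts.get(ch, 0) + 1
    if n_x:
        logger.warning(
            "record %r: excluded %d unknown residue(s) X from counts", record.id, n_x
        )
    return counts


def _channel_totals(
    counts: dict[str, float], scheme: HydrolysisScheme
) -> dict[str, float]:
    """Recovery-weighted channel totals for a residue count mapping."""
    totals = {ch: 0.0 for ch in scheme.channels}
    for res, n in counts.items():
        if res == "B":
            if scheme.name == "intact":
                raise ValueError(
                    "ambiguity code B has no channel under the intact scheme"
                )
            totals["Asx"] += n * scheme.recovery["D"]
        elif res == "Z":
            if scheme.name == "intact":
                raise ValueError(
                    "ambiguity code Z has no channel under the intact scheme"
                )
            totals["Glx"] += n * scheme.recovery["E"]
        else:
            totals[scheme.channel_map[res]] += n * scheme.recovery[res]
    return totals


def _normalize(
    totals: dict[str, float], scheme: HydrolysisScheme, n_residues=None
) -> CompositionVector:
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no recoverable residues")
    fractions = {ch: totals[ch] / grand for ch in scheme.channels}
    return CompositionVector(
        scheme_name=scheme.name, fractions=fractions, n_residues=n_residues
    )


def protein_composition(
    record: ProteinRecord, scheme: HydrolysisScheme
) -> CompositionVector:
    """Mole-fraction composition of one protein under a hydrolysis scheme.

    Channel fraction = recovery-weighted residue count of the channel divided
    by the total recovered count; a sequence with no recoverable residues
    (e.g. all-Trp under HCl) is an error.
    """
    counts = residue_counts(record)
    totals = _channel_totals(counts, scheme)
    return _normalize(totals, scheme, n_residues=sum(counts.values()))


def mixture_composition(
    components: list[tuple[ProteinRecord, float]],
    scheme: HydrolysisScheme,
    weight_mode: str = "molar_chain",
) -> CompositionVector:
    """Composition of a weighted protein mixture.

    In ``molar_chain`` mode weights are chain-molar amounts: each component
    contributes weight x residue count per channel.  In ``mass`` mode each
    weight is first divided by the component's chain mass to obtain a molar
    amount.  Weights must be non-negative and not all zero.
    """
    if not components:
        raise ValueError("empty component list")
    if weight_mode not in ("molar_chain", "mass"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if any(w < 0 for _, w in components):
        raise ValueError("negative component weight")
    if all(w == 0 for _, w in components):
        raise ValueError("all component weights are zero")
    totals = {ch: 0.0 for ch in scheme.channels}
    for record, w in components:
        if w == 0:
            continue
        if weight_mode == "mass":
            w = w / molecular_weight(record, mode="chain")
        for ch, t in _channel_totals(residue_counts(record), scheme).items():
            totals[ch] += w * t
    return _normalize(totals, scheme)


def molecular_weight(residue_or_record, mode: str = "free") -> float:
    """Molecular weight in g/mol.

    ``free`` mode on a one-letter residue returns the free amino-acid mass
    (e.g. Gln 146.15, Glu 147.13).  ``chain`` mode on a record returns the
    polymer mass: sum of residue masses plus one water.  Ambiguity codes
    other than U have no defined mass.
    """
    if mode not in ("free", "chain"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(residue_or_record, ProteinRecord):
        seq = residue_or_record.sequence
        total = 0.0
        for ch in seq:
            total += residue_mass(ch)  # raises for B/Z/X
        return total + WATER_MASS
    residue = residue_or_record
    if mode == "free":
        return free_mass(residue)
    return residue_mass(residue) + WATER_MASS  # single residue as length-1 chain


def load_construct_fixture() -> ProteinRecord:
    """Packaged polyglutamine positive-control construct (190Q), a synthetic
    reconstruction of the huntingtin-exon1-EGFP fusion expressed in the HD
    model (see the FASTA header)."""
    from depositcomp.sequence_io import read_fasta

    ref = resources.files("depositcomp.data").joinpath("nhtt_egfp_190q.synthetic.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)[0]


def _longest_q_run(seq: str) -> tuple[int, int]:
    best_start = best_len = 0
    i = 0
    while i < len(seq):
        if seq[i] == "Q":
            j = i
            while j < len(seq) and seq[j] == "Q":
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_len == 0:
        raise ValueError("no polyglutamine tract found")
    return best_start, best_len


def construct_nhtt_egfp(polyq_length: int) -> ProteinRecord:
    """The huntingtin-exon1-EGFP construct with its polyglutamine tract set to
    *polyq_length* residues; all non-tract sequence is identical between any
    two lengths."""
    if polyq_length < 1:
        raise ValueError("polyq_length must be >= 1")
    base = load_construct_fixture()
    start, length = _longest_q_run(base.sequence)
    seq = base.sequence[:start] + "Q" * polyq_length + base.sequence[start + length:]
    return ProteinRecord(
        id=f"nHTT-EGFP_{polyq_length}Q",
        sequence=seq,
        description=f"nHTT-EGFP_{polyq_length}Q huntingtin exon1 ({polyq_length}Q) - EGFP fusion",
    )
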