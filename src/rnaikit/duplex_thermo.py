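"""Nearest-neighbor duplex-end thermodynamics and guide-strand selection.

Which strand of an siRNA duplex is loaded into RISC as the guide is largely
determined by the asymmetry of the duplex ends: the strand whose 5' end is
*less* stably paired (higher free energy) is preferred, and a 5'-terminal U
or A on a strand predisposes it to become the guide, especially when the
opposite strand starts with G or C.  Both criteria are implemented here.

End stability is quantified as the sum of the nearest-neighbor stacking free
energies (dG37, kcal/mol) of the terminal base pairs at a duplex end — by
default the first three nucleotides, i.e. two stacking terms.  Dangling ends
and terminal-AU penalties are deliberately omitted: the quantity is a local
end-stability score, not a full hybridization energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .sirna_enumeration import SiRNADuplex

#: Gas constant in kcal/(mol*K).
R_KCAL = 0.0019872

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

ANTISENSE_5P = "antisense_5p"
SENSE_5P = "sense_5p"

GUIDE_ANTISENSE = "antisense"
GUIDE_SENSE = "sense"
GUIDE_UNDECIDED = "undecided"


def load_stack_table() -> dict[str, float]:
    """Load the packaged dG37 stacking table (key ``XY/ZW`` -> kcal/mol)."""
    text = (
        resources.files("rnaikit.data").joinpath("rna_stack_dg37.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


@dataclass(frozen=True)
class NearestNeighborModel:
    """Stacking free energies with the thermal energy at 37 degrees C."""

    stack_energy: dict[str, float] = field(default_factory=load_stack_table)
    temperature_c: float = 37.0

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kcal/mol (~0.6163 at 37 C)."""
        return R_KCAL * (self.temperature_c + 273.15)

    def wc_stack(self, x: str, y: str) -> float:
        """Stack of two Watson-Crick pairs given the top dinucleotide 5'-xy-3'."""
        key = f"{x}{y}/{_COMPLEMENT[x]}{_COMPLEMENT[y]}"
        try:
            return self.stack_energy[key]
        except KeyError:
            raise KeyError(f"missing stack parameter {key!r}") from None

    def stack(self, top: str, bottom: str) -> float:
        """General stack lookup: top strand 5'->3', bottom written 3'->5'."""
        key = f"{top}/{bottom}"
        try:
            return self.stack_energy[key]
        except KeyError:
            raise KeyError(f"missing stack parameter {key!r}") from None


@lru_cache(maxsize=1)
def default_model() -> NearestNeighborModel:
    return NearestNeighborModel()


def end_mfe(
    duplex: SiRNADuplex,
    end: str,
    n_terminal: int = 3,
    model: NearestNeighborModel | None = None,
) -> float:
    """Free energy of the terminal ``n_terminal``-nt sub-duplex at one end.

    ``end`` selects which strand's 5' terminus the window is anchored at
    (``"antisense_5p"`` or ``"sense_5p"``).  The value is the sum of the
    ``n_terminal - 1`` nearest-neighbor stacks read into the duplex from
    that terminus; since the duplex is perfectly complementary by
    construction, each stack is determined by the strand's dinucleotide.
    """
    if not 2 <= n_terminal <= 5:
        raise ValueError("n_terminal must be between 2 and 5")
    model = model or default_model()
    if end == ANTISENSE_5P:
        strand = duplex.antisense
    elif end == SENSE_5P:
        strand = duplex.sense
    else:
        raise ValueError(f"unknown duplex end {end!r}")
    return sum(
        model.wc_stack(strand[i], strand[i + 1]) for i in range(n_terminal - 1)
    )


@dataclass(frozen=True)
class EndStability:
    """End free energies of a duplex and their guide-passenger difference.

    ``delta_mfe = guide_5p_mfe - passenger_5p_mfe`` (guide = antisense);
    positive values mean the guide 5' end is the less stable one, which
    favors loading of the antisense strand.
    """

    guide_5p_mfe: float
    passenger_5p_mfe: float
    n_terminal: int = 3

    @property
    def delta_mfe(self) -> float:
        return self.guide_5p_mfe - self.passenger_5p_mfe


def compute_end_stability(
    duplex: SiRNADuplex,
    n_terminal: int = 3,
    model: NearestNeighborModel | None = None,
) -> EndStability:
    return EndStability(
        guide_5p_mfe=end_mfe(duplex, ANTISENSE_5P, n_terminal, model),
        passenger_5p_mfe=end_mfe(duplex, SENSE_5P, n_terminal, model),
        n_terminal=n_terminal,
    )


@dataclass(frozen=True)
class StrandSelectionVerdict:
    """Outcome of the sequence and thermodynamic strand-selection rules.

    ``sequence_rule_pass``: antisense 5'-terminal nucleotide is U or A.
    ``opposite_end_rule_pass``: sense 5'-terminal nucleotide is G or C
    (a reinforcing signal, required by neither mode by default).
    ``thermo_rule_pass``: the antisense 5' end is less stable than the
    sense 5' end (``delta_mfe > 0``).
    ``strict_thermo_pass``: the asymmetry exceeds the margin
    (``delta_mfe > dmfe_threshold``, default 1 kcal/mol).
    """

    sequence_rule_pass: bool
    opposite_end_rule_pass: bool
    thermo_rule_pass: bool
    strict_thermo_pass: bool
    predicted_guide: str
    delta_mfe: float
    end_stability: EndStability

    def __post_init__(self) -> None:
        if self.strict_thermo_pass and not self.thermo_rule_pass:
            raise ValueError("strict thermo rule implies the plain thermo rule")


def strand_selection(
    duplex: SiRNADuplex,
    model: NearestNeighborModel | None = None,
    n_terminal: int = 3,
    dmfe_threshold: float = 1.0,
) -> StrandSelectionVerdict:
    """Apply the combined sequence/thermodynamic strand-selection rules.

    The antisense strand is predicted as guide when either its 5'-terminal
    nucleotide is U/A or its 5' end is the thermodynamically less stable
    one; the sense strand is predicted when the mirror conditions hold for
    it and none holds for the antisense strand; otherwise the call is
    undecided.
    """
    if dmfe_threshold <= 0:
        raise ValueError("dmfe_threshold must be positive")
    stability = compute_end_stability(duplex, n_terminal, model)
    delta = stability.delta_mfe

    sequence_rule = duplex.antisense[0] in "UA"
    opposite_end_rule = duplex.sense[0] in "GC"
    thermo_rule = delta > 0
    strict_thermo = delta > dmfe_threshold

    antisense_favored = sequence_rule or thermo_rule
    sense_favored = duplex.sense[0] in "UA" or delta < 0

    if antisense_favored:
        predicted = GUIDE_ANTISENSE
    elif sense_favored:
        predicted = GUIDE_SENSE
    else:
        predicted = GUIDE_UNDECIDED

    return StrandSelectionVerdict(
        sequence_rule_pass=sequence_rule,
        opposite_end_rule_pass=opposite_end_rule,
        thermo_rule_pass=thermo_rule,
        strict_thermo_pass=strict_thermo,
        predicted_guide=predicted,
        delta_mfe=delta,
        end_stability=stability,
    )
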