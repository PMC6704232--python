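"""High-sensitivity (HS) and high-efficiency (HE) siRNA classification.

Two rule sets serve two workflows.  Off-target search wants to miss as few
functional siRNAs as possible, so the HS rule accepts any duplex whose
strand-selection call favors the antisense (mRNA-complementary) strand.
Construct design wants only potently silencing siRNAs, so the HE rule
additionally demands the full conjunction of the strand rules with the
>1 kcal/mol end-asymmetry margin, plus an accessible target site on the
transcript being scored.  HE-passing siRNAs are therefore always a subset
of HS-passing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .accessibility import AccessibilityParams, AccessibilityProfile, site_accessibility
from .duplex_thermo import GUIDE_ANTISENSE, StrandSelectionVerdict
from .sirna_enumeration import SENSE_MATCH, SiRNADuplex, TargetHit

#: Rule identifiers reported in ``EfficiencyVerdict.reasons``.
RULE_ORIENTATION = "orientation"
RULE_SEQUENCE = "sequence"
RULE_THERMO = "thermo"
RULE_STRICT_THERMO = "strict_thermo"
RULE_OPPOSITE_END = "opposite_end"
RULE_ACCESSIBILITY = "accessibility"


@dataclass(frozen=True)
class EfficiencyVerdict:
    """Per-(siRNA, transcript) classification outcome.

    ``reasons`` lists every HE conjunct that failed;
    ``accessibility_value`` is the site LAP scalar when it was computed.
    """

    hs_pass: bool
    he_pass: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)
    accessibility_value: float | None = None

    def __post_init__(self) -> None:
        if self.he_pass and not self.hs_pass:
            raise ValueError("HE pass must imply HS pass")


def classify_hs(duplex: SiRNADuplex, verdict: StrandSelectionVerdict) -> bool:
    """HS rule: the strand-selection call predicts the antisense guide."""
    return verdict.predicted_guide == GUIDE_ANTISENSE


def classify_he(
    duplex: SiRNADuplex,
    verdict: StrandSelectionVerdict,
    hit: TargetHit,
    profile: AccessibilityProfile,
    params: AccessibilityParams | None = None,
    require_opposite_end: bool = False,
) -> EfficiencyVerdict:
    """HE rule: strict strand selection plus target-site accessibility.

    Requires, for a sense-match hit: antisense 5'-terminal U/A, a less
    stable antisense 5' end, an end-asymmetry margin above the ΔMFE
    threshold, and a site LAP at or above the accessibility threshold.
    The opposite-end G/C rule can optionally be made mandatory.
    Antisense-match hits fail outright: there the guide strand would not
    pair the transcript.
    """
    params = params or profile.params
    hs = classify_hs(duplex, verdict)
    reasons: list[str] = []
    accessibility_value: float | None = None

    if hit.orientation != SENSE_MATCH:
        reasons.append(RULE_ORIENTATION)
    if not verdict.sequence_rule_pass:
        reasons.append(RULE_SEQUENCE)
    if not verdict.thermo_rule_pass:
        reasons.append(RULE_THERMO)
    if not verdict.strict_thermo_pass:
        reasons.append(RULE_STRICT_THERMO)
    if require_opposite_end and not verdict.opposite_end_rule_pass:
        reasons.append(RULE_OPPOSITE_END)
    if hit.orientation == SENSE_MATCH:
        accessibility_value = site_accessibility(profile, hit.position, duplex.k)
        if accessibility_value < params.threshold:
            reasons.append(RULE_ACCESSIBILITY)

    return EfficiencyVerdict(
        hs_pass=hs,
        he_pass=not reasons,
        reasons=tuple(reasons),
        accessibility_value=accessibility_value,
    )
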