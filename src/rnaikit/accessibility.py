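"""Local target-site accessibility from a windowed partition function.

RISC-mediated cleavage requires the siRNA guide strand to base-pair with
its target site, which intramolecular secondary structure of the mRNA can
occlude.  The local accessibility probability (LAP) of a position is the
Boltzmann probability that the ``u``-nt stretch ending at that position is
completely unpaired, computed with a McCaskill-style partition function
inside sliding folding windows of length ``W`` with base-pair span capped
at ``L``, and averaged over all windows that fully contain the stretch.
Values range from 0 (inaccessible) to 1 (fully accessible); the default
parameters are u=8, L=40, W=80 with a decision threshold of 0.1.

The underlying energy model is deliberately reduced: helix nearest-neighbor
stacking terms plus one constant destabilizing penalty per closed loop
(hairpin, interior or multibranch), with hairpin loops of at least three
unpaired nucleotides.  This keeps the algorithmic core — windowed partition
function, span restriction, unpaired-stretch probabilities, window
averaging — exactly testable against exhaustive structure enumeration
under the same model.  Absolute agreement with the full Turner model (as in
RNAplfold) is not a goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .duplex_thermo import NearestNeighborModel, default_model
from .sequence_io import NucleotideSequence

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_ALPHABET = "ACGU"

#: Allowed base pairs (Watson-Crick plus GU wobble).
PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"))


@dataclass(frozen=True)
class AccessibilityParams:
    """Parameters of the windowed accessibility computation.

    ``u``: length of the unpaired stretch whose probability is reported.
    ``span_L``: maximum span of a base pair inside a window.
    ``window_W``: length of the sliding folding window.
    ``threshold``: LAP cutoff used by callers to call a site accessible.
    """

    u: int = 8
    span_L: int = 40
    window_W: int = 80
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if not self.u <= self.span_L <= self.window_W:
            raise ValueError(
                f"required u <= L <= W, got u={self.u}, L={self.span_L}, "
                f"W={self.window_W}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class FoldEnergyModel:
    """Reduced secondary-structure energy model.

    Energy of a structure = sum of nearest-neighbor stacking terms over
    directly stacked pairs + ``loop_penalty`` for every pair whose
    immediately interior positions are not a pair (i.e. one constant
    penalty per closed loop).  Hairpin loops shorter than
    ``hairpin_min_unpaired`` nucleotides are forbidden.
    """

    nn: NearestNeighborModel = field(default_factory=default_model)
    hairpin_min_unpaired: int = 3
    loop_penalty: float = 5.0

    def tables(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Boltzmann-factor lookup tables for the numeric kernel.

        Returns (pair_ok[5,5], stack_bf[5,5,5,5], loop_bf).  Index 4 is the
        "unpairable" code for ambiguous symbols.
        """
        rt = self.nn.rt
        pair_ok = np.zeros((5, 5), dtype=np.bool_)
        for x, y in PAIRS:
            pair_ok[_BASE_INDEX[x], _BASE_INDEX[y]] = True
        stack_bf = np.ones((5, 5, 5, 5), dtype=np.float64)
        for x, z in PAIRS:  # outer pair x.z
            for y, w in PAIRS:  # inner pair y.w
                dg = self.nn.stack(x + y, z + w)
                stack_bf[
                    _BASE_INDEX[x], _BASE_INDEX[y], _BASE_INDEX[z], _BASE_INDEX[w]
                ] = np.exp(-dg / rt)
        loop_bf = float(np.exp(-self.loop_penalty / rt))
        return pair_ok, stack_bf, loop_bf


@dataclass
class AccessibilityProfile:
    """Per-position local accessibility probabilities of one transcript.

    ``lap[i]`` is the window-averaged probability that the stretch
    ``[i - u + 1, i]`` is entirely unpaired; positions ``< u - 1`` carry
    NaN (no complete stretch ends there).
    """

    transcript_id: str
    lap: np.ndarray
    params: AccessibilityParams

    def __len__(self) -> int:
        return len(self.lap)

    def to_table(self):
        """Defined positions as a tidy table with 1-based coordinates."""
        import pandas as pd

        defined = ~np.isnan(self.lap)
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "position": np.nonzero(defined)[0] + 1,
                "lap": self.lap[defined],
            }
        )


def encode_sequence(residues: str) -> np.ndarray:
    """Map residues to integer codes; non-ACGU symbols become the
    unpairable code 4."""
    return np.array(
        [_BASE_INDEX.get(b, 4) for b in residues], dtype=np.int8
    )


@njit(cache=False)
def _window_partition(
    enc, i0, n, span, min_hp, pair_ok, stack_bf, loop_bf, mask_lo, mask_hi
):
    """Partition function of window ``[i0, i0+n)``.

    Positions in the closed global interval [mask_lo, mask_hi] are forced
    to stay unpaired (pass mask_lo > mask_hi for no constraint).  Zb[i,j]
    sums structures in which (i,j) is a pair; a pair stacked directly on
    its interior neighbor pair contributes a stacking Boltzmann factor,
    any other pair contributes the loop-closure factor.
    """
    zb = np.zeros((n, n))
    z = np.ones((n + 1, n + 1))  # z[i, j+1] = partition fn of [i, j]; empty = 1
    for j in range(n):
        gj = i0 + j
        for i in range(j, -1, -1):
            gi = i0 + i
            # pairability of (i, j)
            ok = (
                pair_ok[enc[gi], enc[gj]]
                and (j - i) >= min_hp + 1
                and (j - i) <= span
                and not (mask_lo <= gi <= mask_hi)
                and not (mask_lo <= gj <= mask_hi)
            )
            if ok:
                interior = z[i + 1, j]  # [i+1, j-1]
                if j - 1 >= i + 1:
                    zb_inner = zb[i + 1, j - 1]
                else:
                    zb_inner = 0.0
                zb[i, j] = loop_bf * (interior - zb_inner) + (
                    stack_bf[enc[gi], enc[gi + 1], enc[gj], enc[gj - 1]] * zb_inner
                )
            # interval partition function [i, j]
            acc = z[i, j]  # j unpaired
            kmin = i if j - span > i else j - span
            for k in range(kmin, j - min_hp):
                if zb[k, j] > 0.0:
                    acc += z[i, k] * zb[k, j]
            z[i, j + 1] = acc
    return z[0, n]


@njit(cache=False)
def _lap_sums(enc, u, span, wn, min_hp, pair_ok, stack_bf, loop_bf):
    """Accumulate unpaired-stretch probabilities over all sliding windows.

    Returns (sums, counts) indexed by the 3'-most position of each
    u-stretch; the profile is sums/counts.
    """
    n = enc.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for w in range(n - wn + 1):
        z_full = _window_partition(
            enc, w, wn, span, min_hp, pair_ok, stack_bf, loop_bf, 1, 0
        )
        for a in range(wn - u + 1):
            lo = w + a
            hi = lo + u - 1
            z_free = _window_partition(
                enc, w, wn, span, min_hp, pair_ok, stack_bf, loop_bf, lo, hi
            )
            sums[hi] += z_free / z_full
            counts[hi] += 1
    return sums, counts


def partition_unpaired(
    seq: NucleotideSequence,
    params: AccessibilityParams | None = None,
    model: FoldEnergyModel | None = None,
) -> AccessibilityProfile:
    """Compute the LAP profile of a transcript.

    For every folding window of length ``min(W, len)`` sliding by one
    nucleotide, the probability that each ``u``-stretch inside the window
    is entirely unpaired is obtained as a ratio of constrained to
    unconstrained partition functions; probabilities are averaged with
    equal weight over all windows fully containing the stretch, and the
    average is assigned to the stretch's 3'-most position.
    """
    params = params or AccessibilityParams()
    model = model or FoldEnergyModel()
    n = len(seq)
    if n < params.u:
        raise ValueError(
            f"sequence {seq.identifier!r} shorter than stretch length u={params.u}"
        )
    enc = encode_sequence(seq.residues)
    pair_ok, stack_bf, loop_bf = model.tables()
    wn = min(params.window_W, n)
    sums, counts = _lap_sums(
        enc,
        params.u,
        params.span_L,
        wn,
        model.hairpin_min_unpaired,
        pair_ok,
        stack_bf,
        loop_bf,
    )
    lap = np.full(n, np.nan)
    defined = counts > 0
    lap[defined] = sums[defined] / counts[defined]
    # Clip tiny numerical excursions outside [0, 1].
    lap[defined] = np.clip(lap[defined], 0.0, 1.0)
    return AccessibilityProfile(seq.identifier, lap, params)


def site_accessibility(
    profile: AccessibilityProfile, site_start: int, k: int
) -> float:
    """Accessibility scalar of a target site: the maximum defined LAP over
    ``[site_start, site_start + k)`` (0-based).

    Callers compare the value against ``profile.params.threshold``; a site
    is accessible as soon as it contains one stretch above threshold.
    """
    n = len(profile.lap)
    if site_start < 0 or site_start + k > n:
        raise IndexError(
            f"site [{site_start}, {site_start + k}) outside profile of length {n}"
        )
    window = profile.lap[site_start : site_start + k]
    if np.all(np.isnan(window)):
        raise ValueError("no defined accessibility value inside the site")
    return float(np.nanmax(window))
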