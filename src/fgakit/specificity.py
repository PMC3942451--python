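"""Probe specificity metrics: identity, continuous stretch, duplex free energy.

Cross-hybridization risk of an oligo probe against a non-target sequence is
screened with three complementary statistics:

* **best identity** — highest percent identity of the probe against any
  same-length window of the subject (either strand), with the probe length
  as denominator;
* **continuous stretch** — the longest exact substring shared with the
  subject (either strand); long perfect stretches hybridize even when
  overall identity is low;
* **duplex free energy** — a nearest-neighbor ΔG°37 estimate of the most
  stable ungapped probe/subject duplex; more negative means more stable,
  hence riskier for a non-target.

The ΔG model is deliberately simple and reproducible: stacking terms are
summed over adjacent positions where *both* bases are Watson-Crick matched,
plus a per-terminal initiation penalty when the corresponding window
terminal is matched.  Mismatch-adjacent steps contribute 0; no loop or
dangling-end terms.  This is an approximation of a full duplex model,
chosen because it is exactly checkable against a brute-force oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio_db import revcomp

R_GAS = 1.98717e-3  # kcal/(K*mol)
_N = ord("N")

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stack and initiation parameters (unified DNA set).

    ``stack_*`` map the 5'->3' probe dinucleotide step to its value for the
    perfectly matched duplex; a step and its reverse complement share one
    value.  Initiation is per matched terminal base pair (A·T vs G·C).
    """

    stack_dh: dict[str, float]
    stack_ds: dict[str, float]
    stack_dg: dict[str, float]
    init_at_dh: float
    init_at_ds: float
    init_at_dg: float
    init_gc_dh: float
    init_gc_ds: float
    init_gc_dg: float

    def init_dg(self, base: str) -> float:
        if base in "AT":
            return self.init_at_dg
        if base in "GC":
            return self.init_gc_dg
        return 0.0  # N never matches; never applied


def load_nn_params() -> NNParameterSet:
    """Load the packaged unified oligonucleotide ΔH/ΔS/ΔG°37 table."""
    dh: dict[str, float] = {}
    ds: dict[str, float] = {}
    dg: dict[str, float] = {}
    init = {}
    text = resources.files("fgakit.data").joinpath("nn_unified_dna.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("step\t"):
            continue
        key, h, s, g = line.split("\t")
        if key.startswith("init_"):
            init[key] = (float(h), float(s), float(g))
        else:
            dh[key], ds[key], dg[key] = float(h), float(s), float(g)
    # consistency: a step and its reverse complement share one value
    for step in dg:
        rc = revcomp(step)
        assert abs(dg[step] - dg[rc]) < 1e-9, (step, rc)
    return NNParameterSet(
        stack_dh=dh,
        stack_ds=ds,
        stack_dg=dg,
        init_at_dh=init["init_AT"][0],
        init_at_ds=init["init_AT"][1],
        init_at_dg=init["init_AT"][2],
        init_gc_dh=init["init_GC"][0],
        init_gc_ds=init["init_GC"][1],
        init_gc_dg=init["init_GC"][2],
    )


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_nn_params() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_nn_params()
    return _DEFAULT_PARAMS


@dataclass
class AlignmentHit:
    """Worst-case alignment of a probe against one subject sequence."""

    probe_id: str
    subject_id: str
    strand: str = "+"
    identity: float = 0.0  # percent of probe length
    stretch: int = 0  # bases
    dg: float = 0.0  # kcal/mol
    subject_start: int = -1
    subject_end: int = -1


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# continuous stretch
# ---------------------------------------------------------------------------

def _substr_set(s: str, length: int) -> set[str]:
    return {
        s[i : i + length]
        for i in range(len(s) - length + 1)
        if "N" not in s[i : i + length]
    }


def _lcs_one_strand(a: str, b: str) -> int:
    """Exact longest common substring by binary search on shared length."""
    lo, hi = 0, min(len(a), len(b))
    # shorter string provides the candidate set
    if len(b) < len(a):
        a, b = b, a
    while lo < hi:
        mid = (lo + hi + 1) // 2
        cands = _substr_set(a, mid)
        found = False
        if cands:
            for i in range(len(b) - mid + 1):
                if b[i : i + mid] in cands:
                    found = True
                    break
        if found:
            lo = mid
        else:
            hi = mid - 1
    return lo


def longest_common_substring(a: str, b: str, both_strands: bool = False) -> int:
    """Length of the longest exact substring shared by ``a`` and ``b``.

    N matches nothing (windows containing N are excluded).  With
    ``both_strands`` the reverse complement of ``b`` is also considered.
    """
    if not a or not b:
        warnings.warn("longest_common_substring called with empty input; returning 0")
        return 0
    best = _lcs_one_strand(a, b)
    if both_strands:
        best = max(best, _lcs_one_strand(a, revcomp(b)))
    return best


# ---------------------------------------------------------------------------
# best identity
# ---------------------------------------------------------------------------

def _match_matrix(probe: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Boolean (n_windows, len(probe)) match matrix; N matches nothing."""
    L = probe.size
    windows = np.lib.stride_tricks.sliding_window_view(subject, L)
    return (windows == probe) & (windows != _N)


def _best_identity_one_strand(probe: np.ndarray, subject: np.ndarray) -> tuple[int, int]:
    """(max matches, leftmost best offset) over full-length windows."""
    L = probe.size
    if subject.size >= L:
        counts = _match_matrix(probe, subject).sum(axis=1)
    else:
        # subject shorter than probe: slide the subject along the probe
        m = _match_matrix(subject, probe)  # windows of the probe
        counts = m.sum(axis=1)
    off = int(np.argmax(counts))
    return int(counts[off]), off


def best_identity(
    probe: str, subject: str, probe_id: str = "", subject_id: str = ""
) -> tuple[float, AlignmentHit]:
    """Highest percent identity of the probe against any subject window.

    Exhaustive ungapped scan of every same-length window on both strands of
    the subject; denominator is the probe length.  Leftmost best window
    wins ties; the forward strand wins a cross-strand tie.
    """
    p = encode(probe)
    L = p.size
    best_m, best_off, best_strand = -1, -1, "+"
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        m, off = _best_identity_one_strand(p, encode(subj))
        if m > best_m:
            best_m, best_off, best_strand = m, off, strand
    identity = 100.0 * best_m / L
    start = best_off
    if best_strand == "-" and len(subject) >= L:
        start = len(subject) - L - best_off  # forward-strand coordinate
    hit = AlignmentHit(
        probe_id=probe_id,
        subject_id=subject_id,
        strand=best_strand,
        identity=identity,
        subject_start=start,
        subject_end=start + min(L, len(subject)),
    )
    return identity, hit


# ---------------------------------------------------------------------------
# duplex free energy
# ---------------------------------------------------------------------------

def duplex_delta_g(
    probe: str, subject_window: str, params: NNParameterSet | None = None
) -> float:
    """ΔG°37 (kcal/mol) of the ungapped duplex of probe vs an equal-length
    same-sense window.

    A position is matched when the window base equals the probe base
    (i.e. the window's complement pairs with the probe).  Stacks count only
    where both adjacent positions match; initiation applies per matched
    window terminal.  Fully mismatched windows score 0.
    """
    if len(probe) != len(subject_window):
        raise ValueError("probe and subject window must have equal length")
    params = params or default_nn_params()
    match = [
        a == b and a != "N" for a, b in zip(probe, subject_window)
    ]
    dg = 0.0
    for i in range(len(probe) - 1):
        if match[i] and match[i + 1]:
            dg += params.stack_dg[probe[i : i + 2]]
    if match[0]:
        dg += params.init_dg(probe[0])
    if match[-1]:
        dg += params.init_dg(probe[-1])
    return dg


def _step_dg_vector(probe: str, params: NNParameterSet) -> np.ndarray:
    g = np.zeros(len(probe) - 1)
    for i in range(len(probe) - 1):
        step = probe[i : i + 2]
        if "N" not in step:
            g[i] = params.stack_dg[step]
    return g


def min_delta_g(
    probe: str,
    subject: str,
    params: NNParameterSet | None = None,
    probe_id: str = "",
    subject_id: str = "",
) -> tuple[float, AlignmentHit]:
    """Most negative duplex ΔG°37 of the probe against any same-length
    window on either strand of the subject (vectorized window scan)."""
    params = params or default_nn_params()
    p = encode(probe)
    L = p.size
    g = _step_dg_vector(probe, params)
    init0 = params.init_dg(probe[0]) if probe[0] != "N" else 0.0
    init1 = params.init_dg(probe[-1]) if probe[-1] != "N" else 0.0
    best = (0.0, -1, "+")
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        s = encode(subj)
        if s.size < L:
            continue
        m = _match_matrix(p, s)
        stacked = m[:, :-1] & m[:, 1:]
        dg = stacked @ g + init0 * m[:, 0] + init1 * m[:, -1]
        off = int(np.argmin(dg))
        if dg[off] < best[0]:
            best = (float(dg[off]), off, strand)
    dg_val, off, strand = best
    start = off
    if strand == "-" and off >= 0:
        start = len(subject) - L - off
    hit = AlignmentHit(
        probe_id=probe_id,
        subject_id=subject_id,
        strand=strand,
        dg=dg_val,
        subject_start=start,
        subject_end=start + L if off >= 0 else -1,
    )
    return dg_val, hit


# ---------------------------------------------------------------------------
# melting temperature & self structure
# ---------------------------------------------------------------------------

def melting_temp(
    probe: str,
    params: NNParameterSet | None = None,
    conc: float = 1e-6,
    salt: float = 1.0,
) -> float:
    """Perfect-duplex nearest-neighbor melting temperature in °C.

    Tm = ΔH / (ΔS + R ln(Cт/4)) − 273.15 + 16.6 log10([Na+]), with total
    strand concentration ``conc`` (mol/L, non-self-complementary duplex
    assumed) and monovalent salt ``salt`` (mol/L).
    """
    params = params or default_nn_params()
    dh = ds = 0.0
    for i in range(len(probe) - 1):
        step = probe[i : i + 2]
        dh += params.stack_dh[step]
        ds += params.stack_ds[step]
    for base in (probe[0], probe[-1]):
        if base in "AT":
            dh += params.init_at_dh
            ds += params.init_at_ds
        else:
            dh += params.init_gc_dh
            ds += params.init_gc_ds
    tm_k = (dh * 1000.0) / (ds + 1000.0 * R_GAS * math.log(conc / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(salt)


def gc_content(seq: str) -> float:
    """GC fraction of a sequence as a percentage."""
    if not seq:
        return 0.0
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def homopolymer_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def self_structure(probe: str) -> tuple[int, int]:
    """(longest self-complementary run, longest homopolymer run).

    The self-complementary run is the longest substring of the probe whose
    reverse complement also occurs in the probe — a fold-back/dimer risk
    proxy.
    """
    if not probe:
        return 0, 0
    return longest_common_substring(probe, revcomp(probe)), homopolymer_run(probe)
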