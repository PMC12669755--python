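"""Low-complexity segment discovery and FG/GF dipeptide bias scoring.

Glycine-rich (or any focus-residue-rich) segments are found with a
low-probability subsequence scan: every window of length 15-500 whose
focus-residue count has a binomial upper-tail probability at most
``p_max`` under the background composition is a candidate; overlapping
candidates are merged and each merged region is trimmed to its
minimal-p core subwindow. Each reported segment is then scored for
FG/GF dipeptide enrichment with a binomial upper tail on overlapping
dipeptide positions (n-1 trials for an n-residue segment) against a
background dipeptide frequency, at a fixed probability threshold of
0.005 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegmentScanParams",
    "BiasedSegment",
    "DipeptideReport",
    "find_biased_segments",
    "dipeptide_enrichment",
    "scan_fasta",
    "default_dipeptide_freq",
]

VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class SequenceAlphabetError(ValueError):
    """Sequence contains a symbol outside the amino-acid alphabet."""


@dataclass
class SegmentScanParams:
    """Window-scan parameters for focus-residue-rich segment discovery."""

    focus_residue: str = "G"
    background_freq: float = 0.0691  # eukaryotic proteome glycine frequency
    p_max: float = 1e-3
    l_min: int = 15
    l_max: int = 500

    def validate(self) -> None:
        if len(self.focus_residue) != 1 or self.focus_residue not in VALID_ALPHABET:
            raise ValueError("focus_residue must be a single amino-acid letter")
        if not 0 < self.background_freq < 1:
            raise ValueError("background_freq must lie in (0, 1)")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if not 1 <= self.l_min <= self.l_max:
            raise ValueError("need 1 <= l_min <= l_max")


@dataclass
class BiasedSegment:
    """A focus-residue-rich segment (0-based, half-open coordinates)."""

    sequence_id: str
    start: int
    end: int
    focus_residue: str
    residue_count: int
    binomial_p: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DipeptideReport:
    """Dipeptide (FG/GF) enrichment of one segment.

    Dipeptides are counted at overlapping positions (``FGF`` contains
    one FG and one GF); the convention is recorded.
    """

    segment: BiasedSegment | None
    dipeptides: dict[str, int]
    expected: float
    p_value: float
    enriched: bool
    n_trials: int
    background_freq: float
    counting: str = "overlapping"
    error: str | None = field(default=None)


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence.upper()) - VALID_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"invalid amino-acid symbols: {sorted(bad)}"
        )


def _binom_sf_ge(count: np.ndarray, n, p: float) -> np.ndarray:
    """P(X >= count) for X ~ Binomial(n, p)."""
    return stats.binom.sf(np.asarray(count) - 1, n, p)


def find_biased_segments(
    sequence: str,
    sequence_id: str = "",
    params: SegmentScanParams | None = None,
) -> list[BiasedSegment]:
    """Scan all windows for focus-residue compositional bias.

    A window of length L in ``[l_min, l_max]`` is a candidate when the
    binomial upper-tail probability of observing at least its focus
    count in L trials at the background frequency is <= ``p_max``.
    Overlapping candidate windows are merged; each merged region is
    trimmed to its minimal-p subwindow (ties broken toward longer,
    then earlier windows). Output segments are sorted by start and
    non-overlapping. ``X`` is tolerated in sequences but never counted
    as the focus residue.
    """
    params = params or SegmentScanParams()
    params.validate()
    seq = sequence.upper()
    if not seq:
        return []
    _check_alphabet(seq)
    n = len(seq)
    is_focus = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(params.focus_residue)
    prefix = np.concatenate([[0], np.cumsum(is_focus)])

    # candidate windows, vectorized per length
    candidates: list[tuple[int, int]] = []
    for L in range(params.l_min, min(params.l_max, n) + 1):
        counts = prefix[L:] - prefix[:-L]
        pvals = _binom_sf_ge(counts, L, params.background_freq)
        for s in np.flatnonzero(pvals <= params.p_max):
            candidates.append((int(s), int(s) + L))
    if not candidates:
        return []

    # merge overlapping candidate windows into regions
    candidates.sort()
    regions = []
    cur_s, cur_e = candidates[0]
    for s, e in candidates[1:]:
        if s < cur_e:
            cur_e = max(cur_e, e)
        else:
            regions.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    regions.append((cur_s, cur_e))

    # trim each region to its minimal-p core subwindow
    segments = []
    for rs, re_ in regions:
        best = None  # (p, -L, start)
        for L in range(params.l_min, min(params.l_max, re_ - rs) + 1):
            starts = np.arange(rs, re_ - L + 1)
            counts = prefix[starts + L] - prefix[starts]
            pvals = _binom_sf_ge(counts, L, params.background_freq)
            i = int(np.lexsort((starts, -np.full_like(starts, L), pvals))[0])
            key = (float(pvals[i]), -L, int(starts[i]))
            if best is None or key < best:
                best = key
        p, negL, s = best
        L = -negL
        segments.append(
            BiasedSegment(
                sequence_id=sequence_id,
                start=s,
                end=s + L,
                focus_residue=params.focus_residue,
                residue_count=int(prefix[s + L] - prefix[s]),
                binomial_p=p,
            )
        )
    segments.sort(key=lambda seg: seg.start)
    return segments


def default_dipeptide_freq(dipeptides=("FG", "GF")) -> float:
    """Summed background frequency of the queried dipeptides under an
    independence model over the eukaryotic proteome composition."""
    from .simulate import DEFAULT_AA_FREQ

    total = sum(DEFAULT_AA_FREQ.values())
    freq = {a: f / total for a, f in DEFAULT_AA_FREQ.items()}
    return float(sum(freq[d[0]] * freq[d[1]] for d in dipeptides))


def dipeptide_enrichment(
    segment_text: str,
    dipeptides: tuple[str, ...] = ("FG", "GF"),
    background_dipeptide_freq: float | None = None,
    threshold: float = 0.005,
    segment: BiasedSegment | None = None,
) -> DipeptideReport:
    """Binomial upper-tail enrichment of dipeptides in a segment.

    Overlapping dipeptide positions 0..len-2 are counted; the tail is
    ``P(X >= observed)`` for ``X ~ Binomial(len-1, f)`` where ``f`` is
    the summed background frequency of the queried dipeptides.
    """
    seq = segment_text.upper()
    if len(seq) < 2:
        raise ValueError("segment must have length >= 2")
    _check_alphabet(seq)
    f = (
        background_dipeptide_freq
        if background_dipeptide_freq is not None
        else default_dipeptide_freq(dipeptides)
    )
    if not 0 < f < 1:
        raise ValueError("background dipeptide frequency must lie in (0, 1)")

    counts = {d: 0 for d in dipeptides}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    total = sum(counts.values())
    n_trials = len(seq) - 1
    p = float(_binom_sf_ge(total, n_trials, f)) if total > 0 else 1.0
    return DipeptideReport(
        segment=segment,
        dipeptides=counts,
        expected=n_trials * f,
        p_value=p,
        enriched=p < threshold,
        n_trials=n_trials,
        background_freq=f,
    )


def scan_fasta(
    records,
    scan_params: SegmentScanParams | None = None,
    dipeptides: tuple[str, ...] = ("FG", "GF"),
    background_dipeptide_freq: float | None = None,
    threshold: float = 0.005,
) -> pd.DataFrame:
    """Batch driver: segment discovery + dipeptide scoring per record.

    ``records`` are Biopython SeqRecords or ``(id, sequence)`` pairs.
    Unreadable records produce an error row; the scan continues. The
    output has one row per (sequence, segment), ordered by record then
    segment start, plus one summary row per sequence with the
    ``any_enriched`` flag.
    """
    scan_params = scan_params or SegmentScanParams()
    rows = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = rec.id, str(rec.seq)
        try:
            segments = find_biased_segments(seq, sequence_id=rid, params=scan_params)
            reports = [
                dipeptide_enrichment(
                    seq[s.start : s.end],
                    dipeptides=dipeptides,
                    background_dipeptide_freq=background_dipeptide_freq,
                    threshold=threshold,
                    segment=s,
                )
                for s in segments
            ]
        except SequenceAlphabetError as exc:
            rows.append(
                {"sequence_id": rid, "row_type": "error", "error": str(exc)}
            )
            continue
        for seg, rep in zip(segments, reports):
            row = {
                "sequence_id": rid,
                "row_type": "segment",
                "start": seg.start,
                "end": seg.end,
                "residue_count": seg.residue_count,
                "binomial_p": seg.binomial_p,
                "p_value": rep.p_value,
                "enriched": rep.enriched,
                "error": None,
            }
            for d, c in rep.dipeptides.items():
                row[f"{d}_count"] = c
            rows.append(row)
        rows.append(
            {
                "sequence_id": rid,
                "row_type": "summary",
                "n_segments": len(segments),
                "any_enriched": any(r.enriched for r in reports),
                "error": None,
            }
        )
    return pd.DataFrame(rows)
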