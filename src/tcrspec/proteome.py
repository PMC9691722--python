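"""Sliding-window proteome scan against a specificity fingerprint.

Every 9-residue window whose p2 residue is in the allowed anchor set
(default {M, L}: leucine is tolerated in the B-pocket of HLA-A2) and whose
p9 residue equals the fixed C-terminal anchor is scored; windows containing
nonstandard or ambiguous residues are skipped.  Hits at or above the score
threshold are reported as occurrences, plus a deduplicated unique-peptide
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .constants import AA_INDEX, AMINO_ACIDS, T_STANDARD_K
from .distribution import EDGE_SNAP
from .errors import InvalidParameterError
from .fingerprint import SpecificityFingerprint, kd_from_score

__all__ = ["ProteomeHit", "ProteomeScanResult", "scan_proteome"]


@dataclass(frozen=True)
class ProteomeHit:
    source_id: str
    offset: int  # 0-based window start
    peptide: str
    score: float
    est_kd: float


@dataclass(frozen=True)
class ProteomeScanResult:
    hits: list[ProteomeHit]
    unique_peptides: int
    windows_scored: int

    def __len__(self) -> int:
        return len(self.hits)


def _iter_records(source) -> Iterable[tuple[str, str]]:
    if isinstance(source, (str, Path)):
        for rec in SeqIO.parse(str(source), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for item in source:
            if hasattr(item, "seq"):  # SeqRecord
                yield item.id, str(item.seq)
            else:
                yield item  # (id, sequence) pair


def scan_proteome(
    fp: SpecificityFingerprint,
    source,
    threshold: float = 0.8,
    allowed_p2: frozenset[str] | set[str] = frozenset("ML"),
    temperature: float = T_STANDARD_K,
) -> ProteomeScanResult:
    """Scan protein sequences for anchored nonamers scoring >= threshold.

    ``source`` may be a FASTA path, an iterable of Bio SeqRecords, or an
    iterable of (id, sequence) pairs.  Hits are sorted by descending score,
    ties by (source_id, offset).
    """
    if not (fp.min_score() - 1.0 <= threshold <= fp.max_score() + 1.0):
        raise InvalidParameterError(
            f"threshold {threshold} far outside the scoring range "
            f"[{fp.min_score():.3f}, {fp.max_score():.3f}]"
        )
    n = len(fp.wt_sequence)
    varied = fp.varied_positions
    anchors = fp.anchor_positions
    p9_pos, p9_aa = max(anchors.items())
    allowed_p2 = frozenset(a.upper() for a in allowed_p2)

    # per varied position: residue -> percent contribution
    contrib = [
        {aa: fp.percent[row, AA_INDEX[aa]] for aa in AMINO_ACIDS}
        for row in range(len(varied))
    ]

    hits: list[ProteomeHit] = []
    peptides: set[str] = set()
    windows_scored = 0
    for source_id, seq in _iter_records(source):
        s = seq.upper()
        for off in range(0, len(s) - n + 1):
            window = s[off : off + n]
            if window[1] not in allowed_p2:
                continue
            if window[p9_pos - 1] != p9_aa:
                continue
            if any(c not in AA_INDEX for c in window):
                continue  # nonstandard/ambiguous residue in window
            total = 0.0
            for row, pos in enumerate(varied):
                total += contrib[row][window[pos - 1]]
            score = total / fp.norm_factor
            windows_scored += 1
            if score >= threshold - EDGE_SNAP:
                hits.append(
                    ProteomeHit(
                        source_id=source_id,
                        offset=off,
                        peptide=window,
                        score=float(score),
                        est_kd=kd_from_score(score, fp.dg_wt, temperature),
                    )
                )
                peptides.add(window)

    hits.sort(key=lambda h: (-h.score, h.source_id, h.offset))
    return ProteomeScanResult(
        hits=hits, unique_peptides=len(peptides), windows_scored=windows_scored
    )
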