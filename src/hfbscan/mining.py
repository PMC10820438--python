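"""Typical-hydrophobin mining: skeleton extraction, grammar matching,
classification and proteome screening.

The census logic: a candidate must be 80-400 aa long; its cysteines must
admit an 8-Cys skeleton satisfying the broad ``typical`` spacing grammar
(class I call) or the consensus ``class_II`` grammar; sequences of the
right length whose 6, 7 or 9 cysteines cannot satisfy the typical
grammar are reported as atypical hydrophobin-like candidates. Everything
else is rejected with a reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from itertools import combinations
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from hfbscan.grammars import CysGrammar, default_grammars
from hfbscan.sequence_io import ProteinRecord

__all__ = [
    "GapAssignment",
    "MatchResult",
    "HfbCall",
    "MiningReport",
    "cys_skeleton",
    "match_grammar",
    "classify_hfb",
    "screen_proteome",
]

MIN_LENGTH = 80
MAX_LENGTH = 400
#: Cys counts reported as atypical hydrophobin-like when the typical
#: grammar cannot be satisfied.
ATYPICAL_CYS_COUNTS = frozenset({6, 7, 9})
#: Cap on enumerated 8-subsets of cysteine positions for Cys-rich input.
MAX_SUBSETS = 5000


def cys_skeleton(seq: str) -> List[int]:
    """0-based positions of every cysteine, in increasing order."""
    return [i for i, aa in enumerate(seq) if aa == "C"]


@dataclass(frozen=True)
class GapAssignment:
    """A choice of 8 skeleton cysteines satisfying a grammar."""

    positions: Tuple[int, ...]  # 8 increasing 0-based positions
    gap_vector: Tuple[int, ...]  # 7 inter-Cys gap lengths
    leader_len: int
    tail_len: int


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    assignment: Optional[GapAssignment] = None
    cap_exceeded: bool = False

    def __bool__(self) -> bool:
        return self.matched


def _check_positions(
    seq: str, pos: Sequence[int], grammar: CysGrammar
) -> Optional[GapAssignment]:
    leader = pos[0]
    tail = len(seq) - pos[-1] - 1
    if not (grammar.leader[0] <= leader <= grammar.leader[1]):
        return None
    if not (grammar.tail[0] <= tail <= grammar.tail[1]):
        return None
    gaps = []
    for (lo, hi), a, b in zip(grammar.gaps, pos, pos[1:]):
        gap = b - a - 1
        if not (lo <= gap <= hi):
            return None
        if grammar.forbid_in_gaps and gap:
            segment = seq[a + 1 : b]
            if any(ch in grammar.forbid_in_gaps for ch in segment):
                return None
        gaps.append(gap)
    return GapAssignment(
        positions=tuple(pos),
        gap_vector=tuple(gaps),
        leader_len=leader,
        tail_len=tail,
    )


def match_grammar(
    seq: str, grammar: CysGrammar, max_subsets: int = MAX_SUBSETS
) -> MatchResult:
    """Best 8-Cys gap assignment of ``seq`` under ``grammar``.

    With exactly 8 cysteines the single possible skeleton is checked
    directly. With more, 8-subsets of the cysteine positions are
    enumerated in lexicographic order (which visits smaller leaders
    first) and the first satisfying assignment is returned; enumeration
    is refused when the subset count exceeds ``max_subsets`` and the
    result carries ``cap_exceeded=True``. Gap lengths count residues
    strictly between consecutive skeleton cysteines; a gap containing a
    letter from ``grammar.forbid_in_gaps`` fails.
    """
    cys = cys_skeleton(seq)
    k = grammar.n_skeleton_cys
    if len(cys) < k:
        return MatchResult(False)
    if len(cys) == k:
        asn = _check_positions(seq, cys, grammar)
        return MatchResult(asn is not None, asn)
    if comb(len(cys), k) > max_subsets:
        return MatchResult(False, cap_exceeded=True)
    for subset in combinations(cys, k):
        asn = _check_positions(seq, subset, grammar)
        if asn is not None:
            return MatchResult(True, asn)
    return MatchResult(False)


@dataclass(frozen=True)
class HfbCall:
    """Per-protein classification outcome."""

    protein_id: str
    n_cys: int
    length: int
    verdict: str  # typical_class_I | class_II | atypical | rejected
    gap_vector: Optional[Tuple[int, ...]] = None
    leader_len: Optional[int] = None
    tail_len: Optional[int] = None
    reject_reason: Optional[str] = None  # length | cys_count | no_grammar_match
    matched_grammar: Optional[str] = None

    @property
    def is_candidate(self) -> bool:
        """True for any hydrophobin candidate (typical, class II or atypical)."""
        return self.verdict in ("typical_class_I", "class_II", "atypical")


def classify_hfb(
    record: ProteinRecord, grammars: Optional[Mapping[str, CysGrammar]] = None
) -> HfbCall:
    """Classify one protein against the typical/class I/class II grammars.

    Precedence: the length window is applied first; the narrower class II
    consensus is tested before the broad typical pattern so that a
    sequence satisfying both is called class II; a typical match is
    reported as typical class I. Right-length sequences with 6, 7 or 9
    cysteines that fail the typical grammar are atypical candidates.
    """
    if grammars is None:
        grammars = default_grammars()
    for required in ("typical", "class_II"):
        if required not in grammars:
            raise ValueError(f"grammar set must include {required!r}")
    seq = record.sequence
    n_cys = seq.count("C")
    length = len(seq)
    base = dict(protein_id=record.id, n_cys=n_cys, length=length)

    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        return HfbCall(**base, verdict="rejected", reject_reason="length")

    m2 = match_grammar(seq, grammars["class_II"])
    if m2:
        a = m2.assignment
        return HfbCall(
            **base,
            verdict="class_II",
            gap_vector=a.gap_vector,
            leader_len=a.leader_len,
            tail_len=a.tail_len,
            matched_grammar="class_II",
        )
    mt = match_grammar(seq, grammars["typical"])
    if mt:
        a = mt.assignment
        return HfbCall(
            **base,
            verdict="typical_class_I",
            gap_vector=a.gap_vector,
            leader_len=a.leader_len,
            tail_len=a.tail_len,
            matched_grammar="typical",
        )
    if n_cys in ATYPICAL_CYS_COUNTS:
        return HfbCall(**base, verdict="atypical")
    reason = "cys_count" if n_cys < min(ATYPICAL_CYS_COUNTS) else "no_grammar_match"
    return HfbCall(**base, verdict="rejected", reject_reason=reason)


@dataclass
class MiningReport:
    """Screening result over a proteome: per-protein calls plus counts."""

    calls: List[HfbCall]
    counts: Dict[str, int]
    annotations: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def n_candidates(self) -> int:
        return sum(
            self.counts.get(v, 0) for v in ("typical_class_I", "class_II", "atypical")
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "protein_id": c.protein_id,
                    "length": c.length,
                    "n_cys": c.n_cys,
                    "verdict": c.verdict,
                    "matched_grammar": c.matched_grammar or "",
                    "gap_vector": ",".join(map(str, c.gap_vector)) if c.gap_vector else "",
                    "leader_len": c.leader_len if c.leader_len is not None else "",
                    "tail_len": c.tail_len if c.tail_len is not None else "",
                    "reject_reason": c.reject_reason or "",
                }
            )
        df = pd.DataFrame(rows)
        if self.annotations is not None:
            df = df.merge(self.annotations, on="protein_id", how="left")
            for col in ("signal_peptide", "sub_location"):
                if col in df.columns:
                    df[col] = df[col].fillna("unknown")
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "counts": self.counts,
            "n_candidates": self.n_candidates,
            "calls": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def screen_proteome(
    records: Iterable[ProteinRecord],
    grammars: Optional[Mapping[str, CysGrammar]] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> MiningReport:
    """Classify every record; report sorted by id with verdict counts.

    ``annotations`` may carry pre-computed external predictions (columns
    ``protein_id``, ``signal_peptide``, ``sub_location``); they are merged
    into the tabular report verbatim and reported as ``unknown`` when
    absent — they are never computed here.
    """
    records = list(records)
    if not records:
        raise ValueError("screen_proteome requires at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    calls = sorted(
        (classify_hfb(r, grammars) for r in records), key=lambda c: c.protein_id
    )
    counts: Dict[str, int] = {}
    for c in calls:
        counts[c.verdict] = counts.get(c.verdict, 0) + 1
    return MiningReport(calls=calls, counts=counts, annotations=annotations)
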