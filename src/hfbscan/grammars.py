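"""Cysteine-spacing grammars for hydrophobin classification.

A hydrophobin grammar constrains the residue counts around an 8-cysteine
skeleton: a leader before the first Cys, seven inter-Cys gaps (the two
adjacent "CC" doublets are fixed 0-length gaps), and a tail after the
last Cys. Gap lengths count residues strictly between consecutive
skeleton cysteines.

Shipped grammars:

``typical``
    The broad census pattern used as the primary filter:
    X2-38 - C - X5-9 - CC - X11-44 - C - X8-23 - C - X5-9 - CC - X6-18 -
    C - X2-14.
``class_I`` / ``class_II``
    The literature consensus patterns used for the subclass call
    (class I: C-X6-7-CC-X33-41-C-X19-25-C-X5-CC-X12-17-C; class II:
    C-X9-10-CC-X11-C-X16-C-X8-9-CC-X10-C), leader and tail
    unconstrained.
``gf_strain``
    The strain-specific *Grifola frondosa* pattern
    C-X7/8-CC-X13-32-C-X12/13-C-X5/6-CC-X11/12-C, shipped as an optional
    extra grammar (not part of the default classification set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import yaml

__all__ = ["CysGrammar", "default_grammars", "load_grammars", "GF_STRAIN"]

Range = Tuple[int, int]

#: Effectively unconstrained range for leaders/tails.
UNBOUNDED: Range = (0, 10_000)


@dataclass(frozen=True)
class CysGrammar:
    """Ordered gap-range constraints over an 8-cysteine skeleton."""

    name: str
    leader: Range = UNBOUNDED
    gaps: Tuple[Range, Range, Range, Range, Range, Range, Range] = ()
    tail: Range = UNBOUNDED
    forbid_in_gaps: frozenset[str] = field(default_factory=lambda: frozenset("C"))

    def __post_init__(self) -> None:
        if len(self.gaps) != 7:
            raise ValueError(f"grammar {self.name!r}: need exactly 7 gap ranges")
        for lo, hi in (self.leader, *self.gaps, self.tail):
            if lo < 0 or lo > hi:
                raise ValueError(
                    f"grammar {self.name!r}: invalid range ({lo}, {hi})"
                )

    @property
    def n_skeleton_cys(self) -> int:
        return 8


def _grammar(name, gaps, leader=UNBOUNDED, tail=UNBOUNDED, forbid="C"):
    return CysGrammar(
        name=name,
        leader=tuple(leader),
        gaps=tuple(tuple(g) for g in gaps),
        tail=tuple(tail),
        forbid_in_gaps=frozenset(forbid),
    )


TYPICAL = _grammar(
    "typical",
    leader=(2, 38),
    gaps=[(5, 9), (0, 0), (11, 44), (8, 23), (5, 9), (0, 0), (6, 18)],
    tail=(2, 14),
)

CLASS_I = _grammar(
    "class_I",
    gaps=[(6, 7), (0, 0), (33, 41), (19, 25), (5, 5), (0, 0), (12, 17)],
)

CLASS_II = _grammar(
    "class_II",
    gaps=[(9, 10), (0, 0), (11, 11), (16, 16), (8, 9), (0, 0), (10, 10)],
)

#: Strain-specific pattern; the 12/13 gap follows the published pattern
#: with its apparent C/X typographical slip read as an X gap.
GF_STRAIN = _grammar(
    "gf_strain",
    gaps=[(7, 8), (0, 0), (13, 32), (12, 13), (5, 6), (0, 0), (11, 12)],
)


def default_grammars(strict_x: bool = False) -> Dict[str, CysGrammar]:
    """The grammar set used for classification.

    ``strict_x=True`` additionally forbids tryptophan inside gaps, as
    the strain pattern's X is sometimes defined to exclude both C and W;
    the default forbids only C.
    """
    grammars = {"typical": TYPICAL, "class_I": CLASS_I, "class_II": CLASS_II}
    if strict_x:
        grammars = {
            name: CysGrammar(
                name=g.name,
                leader=g.leader,
                gaps=g.gaps,
                tail=g.tail,
                forbid_in_gaps=frozenset("CW"),
            )
            for name, g in grammars.items()
        }
    return grammars


def load_grammars(path: str | Path) -> Dict[str, CysGrammar]:
    """Load grammar definitions from a YAML/JSON config.

    Each entry maps a name to ``{leader: [lo, hi], gaps: [[lo, hi] x 7],
    tail: [lo, hi], forbid_in_gaps: "C"}``; leader/tail default to
    unconstrained and forbid_in_gaps to ``"C"``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    grammars: Dict[str, CysGrammar] = {}
    for name, cfg in raw.items():
        grammars[name] = _grammar(
            name,
            gaps=cfg["gaps"],
            leader=tuple(cfg.get("leader", UNBOUNDED)),
            tail=tuple(cfg.get("tail", UNBOUNDED)),
            forbid=cfg.get("forbid_in_gaps", "C"),
        )
    return grammars


def dump_grammars(grammars: Mapping[str, CysGrammar], path: str | Path) -> None:
    """Write a grammar set to YAML (inverse of :func:`load_grammars`)."""
    raw = {
        name: {
            "leader": list(g.leader),
            "gaps": [list(gap) for gap in g.gaps],
            "tail": list(g.tail),
            "forbid_in_gaps": "".join(sorted(g.forbid_in_gaps)),
        }
        for name, g in grammars.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
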