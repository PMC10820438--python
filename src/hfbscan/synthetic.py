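"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: a proteome with
planted grammar-conforming hydrophobins, hydrophobin-like atypical
sequences and decoys; qPCR Ct tables with planted log2 fold changes; and
alignments evolved on a known tree. All randomness flows through one
seeded NumPy generator, so the same seed reproduces byte-identical
outputs.

The shipped census plan (:func:`gf_census_plan`) emulates a basidiomycete
hydrophobin census: 19 typical 8-Cys class I proteins, three atypical
hydrophobin-like proteins (two with 7 and one with 6 cysteines) and 80
decoys, 20% of which are near-misses — sequences whose spacing is one
residue outside the typical grammar. Planted sequences draw their
non-skeleton residues from a hydrophobic-biased alphabet so their GRAVY
lands in the hydrophobic range observed for real class I hydrophobins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hfbscan.grammars import CLASS_II, TYPICAL, CysGrammar
from hfbscan.mining import classify_hfb, cys_skeleton
from hfbscan.physchem import gravy, theoretical_pi
from hfbscan.phylo import Alignment, PhyloTree, TreeNode
from hfbscan.sequence_io import ProteinRecord

__all__ = [
    "CensusPlan",
    "gf_census_plan",
    "generate_proteome",
    "generate_ct_table",
    "generate_msa",
    "random_tree",
]

#: Hydrophobic-biased residue alphabet for planted non-skeleton segments.
#: Excludes C (the skeleton owns every cysteine) and W. Weighted so a
#: planted ~110-mer with its 8 skeleton cysteines averages a GRAVY near
#: the middle of the class I range.
_GAP_LETTERS = "AIVLFMGSTPYNQDEKRH"
_GAP_WEIGHTS = np.array(
    [10, 8, 8, 8, 5, 3, 8, 8, 6, 4, 2, 3, 3, 4, 4, 4, 3, 2], dtype=float
)
_GAP_WEIGHTS /= _GAP_WEIGHTS.sum()

_ALL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_RETRY_CAP = 2000


@dataclass(frozen=True)
class CensusPlan:
    """Composition and constraints of a synthetic hydrophobin census."""

    n_typical_class_I: int = 19
    atypical_cys_counts: Tuple[int, ...] = (7, 7, 6)
    n_decoys: int = 80
    near_miss_fraction: float = 0.2
    length_range: Tuple[int, int] = (80, 400)
    gravy_range: Tuple[float, float] = (0.270, 0.951)
    pi_range: Tuple[float, float] = (3.57, 8.50)
    grammar: CysGrammar = TYPICAL
    seed: int = 42

    @property
    def n_records(self) -> int:
        return self.n_typical_class_I + len(self.atypical_cys_counts) + self.n_decoys

    @property
    def planted_verdict(self) -> str:
        """Verdict the planted grammar-conforming sequences should earn."""
        return "class_II" if self.grammar.name == "class_II" else "typical_class_I"


def gf_census_plan() -> CensusPlan:
    """The shipped census plan: 19 typical + 3 atypical + 80 decoys, seed 42."""
    return CensusPlan()


def _sample_segment(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    idx = rng.choice(len(_GAP_LETTERS), size=length, p=_GAP_WEIGHTS)
    return "".join(_GAP_LETTERS[i] for i in idx)


def _compose(
    rng: np.random.Generator, leader: int, gaps: Sequence[int], tail: int
) -> str:
    parts = [_sample_segment(rng, leader)]
    for gap in gaps:
        parts.append("C")
        parts.append(_sample_segment(rng, gap))
    parts.append("C")
    parts.append(_sample_segment(rng, tail))
    return "".join(parts)


def _sample_spacing(
    rng: np.random.Generator, grammar: CysGrammar
) -> Tuple[int, List[int], int]:
    # effectively unbounded leaders/tails are sampled from a realistic span
    lo, hi = grammar.leader
    leader = int(rng.integers(lo, min(hi, lo + 38) + 1))
    gaps = [int(rng.integers(g_lo, g_hi + 1)) for g_lo, g_hi in grammar.gaps]
    lo, hi = grammar.tail
    tail = int(rng.integers(lo, min(hi, lo + 14) + 1))
    return leader, gaps, tail


def _satisfies_gaps(gaps: Sequence[int], grammar: CysGrammar) -> bool:
    return all(lo <= g <= hi for g, (lo, hi) in zip(gaps, grammar.gaps))


def _plant_typical(rng: np.random.Generator, plan: CensusPlan) -> Tuple[str, List[int]]:
    """A sequence satisfying the plan grammar (and not class II), with
    length, GRAVY and pI inside the plan ranges."""
    plant_is_class_ii = plan.grammar.name == "class_II"
    for _ in range(_RETRY_CAP):
        leader, gaps, tail = _sample_spacing(rng, plan.grammar)
        if not plant_is_class_ii and _satisfies_gaps(gaps, CLASS_II):
            continue
        length = leader + tail + 8 + sum(gaps)
        if not plan.length_range[0] <= length <= plan.length_range[1]:
            continue
        seq = _compose(rng, leader, gaps, tail)
        if not plan.gravy_range[0] <= gravy(seq) <= plan.gravy_range[1]:
            continue
        if not plan.pi_range[0] <= theoretical_pi(seq) <= plan.pi_range[1]:
            continue
        return seq, gaps
    raise RuntimeError("retry cap exceeded while planting a typical sequence")


def _plant_atypical(rng: np.random.Generator, plan: CensusPlan, n_cys: int) -> str:
    """A typical-like sequence with skeleton cysteines knocked out."""
    seq, _ = _plant_typical(rng, plan)
    positions = cys_skeleton(seq)
    to_remove = rng.choice(len(positions), size=8 - n_cys, replace=False)
    chars = list(seq)
    for i in to_remove:
        chars[positions[i]] = "A"
    return "".join(chars)


def _near_miss(rng: np.random.Generator, plan: CensusPlan) -> str:
    """An 8-Cys sequence with exactly one constrained gap off by one."""
    grammar = plan.grammar
    variable = [i for i, (lo, hi) in enumerate(grammar.gaps) if hi > 0]
    for _ in range(_RETRY_CAP):
        leader, gaps, tail = _sample_spacing(rng, grammar)
        i = int(rng.choice(variable))
        lo, hi = grammar.gaps[i]
        if lo == 0 or rng.random() < 0.5:
            gaps[i] = hi + 1
        else:
            gaps[i] = lo - 1
        if _satisfies_gaps(gaps, CLASS_II):
            continue
        length = leader + tail + 8 + sum(gaps)
        if not plan.length_range[0] <= length <= plan.length_range[1]:
            continue
        return _compose(rng, leader, gaps, tail)
    raise RuntimeError("retry cap exceeded while building a near-miss decoy")


def _random_decoy(rng: np.random.Generator, plan: CensusPlan) -> str:
    """A random in-length-range sequence verified to be rejected."""
    lo, hi = plan.length_range
    for _ in range(_RETRY_CAP):
        length = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, len(_ALL_LETTERS), size=length)
        seq = "".join(_ALL_LETTERS[i] for i in idx)
        call = classify_hfb(ProteinRecord(id="_decoy", sequence=seq))
        if call.verdict == "rejected":
            return seq
    raise RuntimeError("retry cap exceeded while sampling a decoy")


def generate_proteome(
    plan: Optional[CensusPlan] = None, seed: Optional[int] = None
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Generate a synthetic proteome and its ground-truth table.

    Returns the records plus a truth frame (protein_id, planted_verdict,
    n_cys, gap_vector, length). Planted sequences satisfy their intended
    grammar by construction; decoys and near-misses are verified against
    the classifier so no decoy overlaps a candidate verdict.
    Deterministic for a fixed seed (default: the plan's own seed).
    """
    plan = plan or gf_census_plan()
    rng = np.random.default_rng(plan.seed if seed is None else seed)

    records: List[ProteinRecord] = []
    truth_rows: List[dict] = []

    def add(pid: str, seq: str, verdict: str, gap_vector: Optional[Sequence[int]]):
        records.append(ProteinRecord(id=pid, sequence=seq))
        truth_rows.append(
            {
                "protein_id": pid,
                "planted_verdict": verdict,
                "n_cys": seq.count("C"),
                "gap_vector": ",".join(map(str, gap_vector)) if gap_vector else "",
                "length": len(seq),
            }
        )

    for i in range(plan.n_typical_class_I):
        seq, gaps = _plant_typical(rng, plan)
        add(f"GF_T{i + 1:02d}", seq, plan.planted_verdict, gaps)

    for i, n_cys in enumerate(plan.atypical_cys_counts):
        seq = _plant_atypical(rng, plan, n_cys)
        add(f"GF_A{i + 1:02d}", seq, "atypical", None)

    n_near = int(round(plan.n_decoys * plan.near_miss_fraction))
    for i in range(plan.n_decoys):
        if i < n_near:
            seq = _near_miss(rng, plan)
            call = classify_hfb(ProteinRecord(id="_nm", sequence=seq))
            if call.verdict != "rejected":  # pragma: no cover - construction guard
                raise RuntimeError("near-miss decoy unexpectedly classified as candidate")
        else:
            seq = _random_decoy(rng, plan)
        add(f"GF_D{i + 1:02d}", seq, "rejected", None)

    truth = pd.DataFrame(truth_rows).sort_values("protein_id").reset_index(drop=True)
    return records, truth


def generate_ct_table(
    effects: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.2,
    seed: int = 0,
    ref_gene: str = "gapdh",
    stages: Sequence[str] = ("Myc", "Pri", "Yfb", "Mfb"),
    n_replicates: int = 3,
    base_ct: float = 26.0,
    ref_base_ct: float = 18.0,
) -> pd.DataFrame:
    """Simulate a Ct table for 4 stages x replicates with planted effects.

    ``effects[gene][stage]`` is the planted log2 fold change relative to
    the first (calibrator) stage; unlisted stages default to 0. A target
    with log2 effect e at a stage has Ct drawn as ``base_ct - e + noise``;
    the reference gene's Ct is constant in expectation across stages.
    """
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": ref_gene,
                    "stage": stage,
                    "replicate": rep,
                    "ct": ref_base_ct + rng.normal(0.0, noise_sd) if noise_sd else ref_base_ct,
                }
            )
    for gene in sorted(effects):
        for stage in stages:
            effect = float(effects[gene].get(stage, 0.0))
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "stage": stage,
                        "replicate": rep,
                        "ct": base_ct - effect + noise,
                    }
                )
    return pd.DataFrame(rows)


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    branch_length_range: Tuple[float, float] = (0.05, 0.25),
    ids: Optional[Sequence[str]] = None,
) -> PhyloTree:
    """A random unrooted binary topology with uniform branch lengths."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    ids = list(ids) if ids is not None else [f"t{i + 1}" for i in range(n_taxa)]
    lo, hi = branch_length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    lineages: List[TreeNode] = [TreeNode(name=name) for name in ids]
    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        joined = TreeNode(children=[(a, bl()), (b, bl())])
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(joined)
    root = TreeNode(children=[(x, bl()) for x in lineages])
    return PhyloTree(root=root, taxa=tuple(ids))


def _evolve(
    node: TreeNode,
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    out: Dict[str, np.ndarray],
) -> None:
    if node.is_leaf:
        out[node.name] = seq
        return
    for child, length in node.children:
        child_seq = seq.copy()
        if rate > 0 and length > 0:
            p_sub = 1.0 - np.exp(-rate * length)
            mask = rng.random(seq.size) < p_sub
            n_sub = int(mask.sum())
            if n_sub:
                # symmetric substitution: uniform over the 19 other letters
                shift = rng.integers(1, 20, size=n_sub)
                child_seq[mask] = (child_seq[mask] + shift) % 20
        _evolve(child, child_seq, rate, rng, out)


def generate_msa(
    n_taxa: int = 12,
    n_columns: int = 500,
    subst_rate: float = 1.0,
    seed: int = 0,
    tree: Optional[PhyloTree] = None,
) -> Tuple[Alignment, PhyloTree]:
    """Evolve a gap-free protein alignment on a (random or given) tree.

    Substitutions are symmetric over the 20 letters: along a branch of
    length t each site changes with probability 1 - exp(-rate * t) to a
    uniformly chosen different letter. Returns the alignment and the
    generating tree for topology-recovery tests.
    """
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = random_tree(n_taxa, rng)
    root_seq = rng.integers(0, 20, size=n_columns)
    leaf_seqs: Dict[str, np.ndarray] = {}
    _evolve(tree.root, root_seq, subst_rate, rng, leaf_seqs)
    rows = tuple(
        "".join(_ALL_LETTERS[i] for i in leaf_seqs[name]) for name in tree.taxa
    )
    return Alignment(tuple(tree.taxa), rows), tree
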