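"""Cross-species phosphosite position transfer by global alignment.

Ortholog protein pairs are aligned with the Needleman-Wunsch global
algorithm (BLOSUM62, affine gaps, via Bio.Align.PairwiseAligner) and the
alignment columns convert 1-based residue positions from the source
species to the target species. Sites falling opposite a target gap are
unalignable and dropped; sites landing on a non-S/T/Y or different target
residue are retained but flagged non-conserved (a switch drops them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .simulate import PHOSPHO_RESIDUES, AMINO_ACIDS

logger = logging.getLogger(__name__)

_VALID = set(AMINO_ACIDS)


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties.

    A gap run of length L scores ``gap_open + (L - 1) * gap_extend``
    (the opening penalty covers the first gapped residue).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass
class OrthologAlignment:
    """A global pairwise alignment plus its source->target position map."""

    source_id: str
    target_id: str
    aligned_source: str
    aligned_target: str
    score: float
    position_map: dict[int, int | None] = field(repr=False)

    @property
    def source_length(self) -> int:
        return len(self.aligned_source.replace("-", ""))


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _position_map_from_gapped(a: str, b: str) -> dict[int, int | None]:
    pmap: dict[int, int | None] = {}
    ai = bi = 0
    for ca, cb in zip(a, b):
        if ca != "-":
            ai += 1
        if cb != "-":
            bi += 1
        if ca != "-":
            pmap[ai] = bi if cb != "-" else None
    return pmap


def needleman_wunsch(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
    source_id: str = "source",
    target_id: str = "target",
) -> OrthologAlignment:
    """Optimal global alignment of two protein sequences.

    Uses BLOSUM62 with affine gap penalties (open -10, extend -0.5) by
    default. When several alignments are co-optimal, the aligner's first
    traceback is taken, which is deterministic for fixed inputs.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} must be nonempty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    aligner = _make_aligner(scoring)
    aln = aligner.align(seq_a, seq_b)[0]
    gapped_a, gapped_b = aln[0], aln[1]
    return OrthologAlignment(
        source_id=source_id,
        target_id=target_id,
        aligned_source=gapped_a,
        aligned_target=gapped_b,
        score=float(aln.score),
        position_map=_position_map_from_gapped(gapped_a, gapped_b),
    )


def transfer_site_position(alignment: OrthologAlignment, source_position: int) -> int | None:
    """Target coordinate of a source residue, or None if it faces a gap."""
    if not 1 <= source_position <= alignment.source_length:
        raise ValueError(
            f"position {source_position} outside 1..{alignment.source_length}"
        )
    return alignment.position_map[source_position]


def map_sites(
    site_fc: pd.DataFrame,
    sequences_source: dict[str, str],
    sequences_target: dict[str, str],
    pairs: dict[str, str],
    scoring: AlignmentScoring | None = None,
    drop_nonconserved: bool = False,
) -> pd.DataFrame:
    """Re-key a collapsed site-FC table into target-species coordinates.

    Each source protein must have exactly one designated ortholog in
    ``pairs``. Unalignable sites are dropped (count logged). Duplicate
    (target protein, position, contrast) rows after mapping are resolved
    by the lowest-p collapse rule. Adds ``residue_conserved``: True when
    the target residue equals the source residue (hence still S/T/Y).
    """
    if site_fc.empty:
        out = site_fc.copy()
        out["residue_conserved"] = pd.Series(dtype=bool)
        return out
    alignments: dict[str, OrthologAlignment] = {}
    for prot in sorted(site_fc["protein"].unique()):
        if prot not in sequences_source:
            raise KeyError(f"protein {prot} missing from source FASTA")
        if prot not in pairs:
            raise KeyError(f"protein {prot} has no ortholog pairing")
        tgt = pairs[prot]
        if tgt not in sequences_target:
            raise KeyError(f"ortholog {tgt} missing from target FASTA")
        alignments[prot] = needleman_wunsch(
            sequences_source[prot],
            sequences_target[tgt],
            scoring,
            source_id=prot,
            target_id=tgt,
        )

    rows = []
    n_unaligned = 0
    for _, row in site_fc.iterrows():
        aln = alignments[row["protein"]]
        tpos = transfer_site_position(aln, int(row["position"]))
        if tpos is None:
            n_unaligned += 1
            continue
        tseq = sequences_target[aln.target_id]
        tres = tseq[tpos - 1]
        conserved = tres == row["residue"] and tres in PHOSPHO_RESIDUES
        if drop_nonconserved and not conserved:
            continue
        new = row.to_dict()
        new.update(
            protein=aln.target_id,
            position=tpos,
            residue=tres,
            source_protein=row["protein"],
            source_position=int(row["position"]),
            residue_conserved=conserved,
        )
        rows.append(new)
    if n_unaligned:
        logger.info("map_sites: %d sites unalignable and dropped", n_unaligned)
    mapped = pd.DataFrame(rows)
    if mapped.empty:
        return mapped
    mapped["_p_order"] = mapped["source_p"].fillna(np.inf)
    mapped["_abs_fc"] = mapped["fc"].abs()
    mapped = mapped.sort_values(
        ["protein", "position", "condition", "timepoint", "_p_order", "_abs_fc", "site_key"],
        ascending=[True, True, True, True, True, False, True],
    ).drop_duplicates(subset=["protein", "position", "condition", "timepoint"], keep="first")
    return mapped.drop(columns=["_p_order", "_abs_fc"]).reset_index(drop=True)
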