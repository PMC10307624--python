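"""Synthetic phosphoproteomics study generator with recorded ground truth.

Emulates the statistical structure of a ligand-stimulation phosphoproteomics
design: replicate log2-intensity measurements of phosphopeptides for two
stimulation ligands at two timepoints against time-matched unstimulated
controls, with planted kinase-level fold-change shifts, per-run offsets
(so median normalization is non-trivial), random missingness, and
orthologous protein sequence pairs whose true residue-position maps are
recorded for recovery tests.

Intensities are generated and stored on the log2 scale; ``linear_scale``
emits ``2**x`` instead to exercise downstream log transforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = frozenset("STY")

# Residue sampling weights: serine/threonine enriched, as in real
# phosphoproteomes, so every protein carries plantable phosphosites.
_AA_WEIGHTS = np.array([2.5 if a in "ST" else (1.5 if a == "Y" else 1.0) for a in AMINO_ACIDS])
_AA_PROBS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

MEASUREMENT_COLUMNS = [
    "peptide_id",
    "protein",
    "site_positions",
    "run",
    "condition",
    "timepoint",
    "replicate",
    "intensity",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Experimental design for the synthetic study.

    Parameters
    ----------
    ligands : stimulation condition labels, each contrasted against the
        time-matched ``control`` condition.
    timepoints : timepoint labels shared by stimulations and controls.
    n_replicates : biological replicates per condition/timepoint (>= 2).
    n_proteins : number of source-species proteins to simulate.
    sites_per_protein : inclusive (lo, hi) range of phosphosites drawn
        per protein.
    noise_sd : replicate-level log2-intensity standard deviation.
    missing_rate : independent drop probability per measurement.
    run_offset_sd : SD of the per-run additive log2 offset (sample-prep
        artifact removed by equal-median normalization).
    linear_scale : emit linear-scale intensities instead of log2.
    seed : master seed; per-stage child generators are derived from it.
    """

    ligands: tuple[str, ...] = ("fibrin", "iC3b")
    timepoints: tuple[str, ...] = ("1h", "3h")
    control: str = "US"
    n_replicates: int = 3
    n_proteins: int = 40
    sites_per_protein: tuple[int, int] = (2, 5)
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    run_offset_sd: float = 0.7
    linear_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        labels = list(self.ligands) + [self.control]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoint labels must be unique")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.ligands) + (self.control,)


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic study.

    ``planted_kinase_deltas`` maps kinase -> {(ligand, timepoint): log2FC
    shift}; ``true_position_maps`` maps source protein id -> {source
    position: target position or None for deleted}; ``substrate_assignment``
    maps kinase -> set of (protein, position, residue) in source-species
    coordinates.
    """

    planted_kinase_deltas: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    true_position_maps: dict[str, dict[int, int | None]] = field(default_factory=dict)
    substrate_assignment: dict[str, set[tuple[int, ...]]] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """Bundle of all generated inputs plus the truth that produced them."""

    design: SimulationDesign
    proteins: dict[str, str]
    orthologs: dict[str, str]
    ortholog_pairs: dict[str, str]
    truth: SyntheticTruth
    sites: list[tuple[str, int, str]]
    measurements: pd.DataFrame
    ks_annotation: pd.DataFrame  # source-species coordinates
    ks_annotation_target: pd.DataFrame  # after true-map transfer


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # child streams by fixed offsets from one master seed
    return np.random.default_rng([stage, seed])


def generate_protein_set(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> dict[str, str]:
    """Generate random protein sequences with guaranteed phospho-acceptor sites.

    Every sequence has length drawn from ``length_range`` (inclusive, min 30)
    and contains at least three S/T/Y residues. Deterministic given ``seed``.
    """
    lo, hi = length_range
    if lo < 30:
        raise ValueError("minimum protein length is 30")
    if hi < lo:
        raise ValueError("length_range must be (lo, hi) with hi >= lo")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins: dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = "".join(rng.choice(aa, size=length, p=_AA_PROBS))
            if sum(seq.count(r) for r in "STY") >= 3:
                break
        proteins[f"PROT{i + 1:04d}"] = seq
    return proteins


def mutate_ortholog(
    sequence: str,
    substitution_rate: float,
    indel_rate: float,
    seed: int = 0,
) -> tuple[str, dict[int, int | None]]:
    """Derive an ortholog by point substitutions and single-residue indels.

    Returns the mutated sequence and the exact source->target position map
    (1-based); deleted source positions map to None. Indels are single
    residues; longer gaps arise only from adjacent events, which keeps the
    map bookkeeping exact. The map is strictly increasing over defined
    entries by construction.
    """
    if not 0 <= substitution_rate <= 0.3:
        raise ValueError("substitution_rate must be in [0, 0.3]")
    if not 0 <= indel_rate <= 0.3:
        raise ValueError("indel_rate must be in [0, 0.3]")
    if not sequence:
        raise ValueError("sequence must be nonempty")
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    out: list[str] = []
    pos_map: dict[int, int | None] = {}
    for i, res in enumerate(sequence, start=1):
        if rng.random() < indel_rate / 2:  # deletion
            pos_map[i] = None
            continue
        new = res
        if rng.random() < substitution_rate:
            choices = [a for a in aa if a != res]
            new = choices[int(rng.integers(len(choices)))]
        out.append(new)
        pos_map[i] = len(out)
        if rng.random() < indel_rate / 2:  # insertion after current residue
            out.append(aa[int(rng.integers(len(aa)))])
    return "".join(out), pos_map


def _choose_sites(
    proteins: dict[str, str],
    sites_per_protein: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[str, int, str]]:
    sites: list[tuple[str, int, str]] = []
    lo, hi = sites_per_protein
    for pid in sorted(proteins):
        seq = proteins[pid]
        acceptors = [i + 1 for i, r in enumerate(seq) if r in PHOSPHO_RESIDUES]
        k = min(int(rng.integers(lo, hi + 1)), len(acceptors))
        chosen = sorted(rng.choice(acceptors, size=k, replace=False).tolist())
        sites.extend((pid, int(p), seq[p - 1]) for p in chosen)
    return sites


def simulate_phospho_experiment(
    design: SimulationDesign,
    truth: SyntheticTruth,
    sites: list[tuple[str, int, str]],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the replicate peptide measurement table.

    Baseline site-group log2 intensities are Normal(mu_site, noise_sd) per
    replicate; substrate sites of planted kinases get their condition's
    delta added; a share of sites is additionally emitted inside
    multiply-phosphorylated peptides; per-run additive offsets are injected.
    Raises if a planted kinase ends with fewer than two measured substrate
    sites.
    """
    if rng is None:
        rng = _stage_rng(design.seed, 3)

    substrate_delta: dict[tuple[str, int], dict[tuple[str, str], float]] = {}
    for kinase, deltas in truth.planted_kinase_deltas.items():
        for prot, pos, _res in truth.substrate_assignment.get(kinase, ()):
            substrate_delta.setdefault((prot, pos), {}).update(deltas)

    # peptide plan: one singly-phosphorylated peptide per site (sometimes
    # two peptides sharing the site set), plus occasional doubly-
    # phosphorylated peptides pairing adjacent sites of one protein
    peptides: list[tuple[str, str, tuple[tuple[int, str], ...]]] = []
    n_pep = 0

    def _add(protein: str, members: tuple[tuple[int, str], ...]) -> None:
        nonlocal n_pep
        n_pep += 1
        peptides.append((f"pep{n_pep:05d}", protein, members))

    by_protein: dict[str, list[tuple[int, str]]] = {}
    for prot, pos, res in sites:
        by_protein.setdefault(prot, []).append((pos, res))
    for prot in sorted(by_protein):
        psites = sorted(by_protein[prot])
        for s in psites:
            _add(prot, (s,))
            if rng.random() < 0.2:  # second peptide, same site set
                _add(prot, (s,))
        for a, b in zip(psites, psites[1:]):
            if rng.random() < 0.25:
                _add(prot, (a, b))

    runs = [
        (f"{cond}_{tp}_r{rep}", cond, tp, rep)
        for cond in design.conditions
        for tp in design.timepoints
        for rep in range(1, design.n_replicates + 1)
    ]
    run_offsets = {r[0]: rng.normal(0.0, design.run_offset_sd) for r in runs}

    site_mu = {(prot, pos): rng.uniform(18.0, 28.0) for prot, pos, _ in sites}

    rows = []
    for pep_id, prot, members in peptides:
        mu = float(np.mean([site_mu[(prot, p)] for p, _ in members]))
        mu += rng.normal(0.0, 0.5)  # peptide-specific response factor
        deltas = [substrate_delta.get((prot, p), {}) for p, _ in members]
        site_str = ";".join(f"{r}{p}" for p, r in members)
        for run, cond, tp, rep in runs:
            if rng.random() < design.missing_rate:
                continue
            shift = max((d.get((cond, tp), 0.0) for d in deltas), default=0.0)
            x = mu + shift + run_offsets[run] + rng.normal(0.0, design.noise_sd)
            rows.append((pep_id, prot, site_str, run, cond, tp, rep, x))

    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if design.linear_scale:
        df["intensity"] = np.exp2(df["intensity"])

    measured = {
        (prot, int(s[1:]))
        for prot, m in zip(df["protein"], df["site_positions"])
        for s in m.split(";")
    }
    for kinase in truth.planted_kinase_deltas:
        n_meas = sum(
            1
            for prot, pos, _res in truth.substrate_assignment.get(kinase, ())
            if (prot, pos) in measured
        )
        if n_meas < 2:
            raise RuntimeError(
                f"planted kinase {kinase} has {n_meas} measured substrate sites (< 2)"
            )
    return df


def simulate_study(
    design: SimulationDesign,
    n_kinases: int = 12,
    substrates_per_kinase: int = 4,
    n_active: int = 3,
    delta: float = 1.5,
    active_conditions: list[tuple[str, str]] | None = None,
    substitution_rate: float = 0.05,
    indel_rate: float = 0.02,
    with_orthologs: bool = True,
) -> SyntheticStudy:
    """Generate a complete synthetic study: sequences, orthologs, kinase
    annotation with planted activity shifts, and the measurement table.

    The first ``n_active`` kinases receive a log2FC shift of ``delta`` on all
    their substrate sites in ``active_conditions`` (default: every
    ligand/timepoint combination). Substrate sets are disjoint across
    kinases so planted effects stay attributable.
    """
    rng_prot = _stage_rng(design.seed, 1)
    rng_orth = _stage_rng(design.seed, 2)
    rng_assign = _stage_rng(design.seed, 4)

    proteins = generate_protein_set(
        design.n_proteins, seed=int(rng_prot.integers(2**31 - 1))
    )
    orthologs: dict[str, str] = {}
    pairs: dict[str, str] = {}
    maps: dict[str, dict[int, int | None]] = {}
    for pid in sorted(proteins) if with_orthologs else []:
        tgt_id = pid.replace("PROT", "HPROT")
        seq, pmap = mutate_ortholog(
            proteins[pid],
            substitution_rate,
            indel_rate,
            seed=int(rng_orth.integers(2**31 - 1)),
        )
        orthologs[tgt_id] = seq
        pairs[pid] = tgt_id
        maps[pid] = pmap

    sites = _choose_sites(proteins, design.sites_per_protein, rng_assign)
    need = n_kinases * substrates_per_kinase
    if need > len(sites):
        raise ValueError(
            f"{need} substrate slots requested but only {len(sites)} sites simulated"
        )
    order = rng_assign.permutation(len(sites))
    assignment: dict[str, set[tuple[str, int, str]]] = {}
    for k in range(n_kinases):
        name = f"KIN{k + 1:03d}"
        idx = order[k * substrates_per_kinase : (k + 1) * substrates_per_kinase]
        assignment[name] = {sites[i] for i in idx}

    if active_conditions is None:
        active_conditions = [
            (lig, tp) for lig in design.ligands for tp in design.timepoints
        ]
    planted = {
        f"KIN{k + 1:03d}": {ct: delta for ct in active_conditions}
        for k in range(n_active)
    }
    truth = SyntheticTruth(
        planted_kinase_deltas=planted,
        true_position_maps=maps,
        substrate_assignment=assignment,
    )

    measurements = simulate_phospho_experiment(design, truth, sites)

    ks_rows = [
        (kin, prot, f"{res}{pos}")
        for kin in sorted(assignment)
        for prot, pos, res in sorted(assignment[kin])
    ]
    ks = pd.DataFrame(ks_rows, columns=["kinase", "protein", "site"])

    tgt_rows = []
    for kin, prot, site in ks_rows if with_orthologs else []:
        pos = int(site[1:])
        tpos = maps[prot].get(pos)
        if tpos is None:
            continue
        tres = orthologs[pairs[prot]][tpos - 1]
        tgt_rows.append((kin, pairs[prot], f"{tres}{tpos}"))
    ks_target = pd.DataFrame(tgt_rows, columns=["kinase", "protein", "site"])

    return SyntheticStudy(
        design=design,
        proteins=proteins,
        orthologs=orthologs,
        ortholog_pairs=pairs,
        truth=truth,
        sites=sites,
        measurements=measurements,
        ks_annotation=ks,
        ks_annotation_target=ks_target,
    )


def simulate_interaction_edges(
    proteins: list[str], edge_prob: float = 0.15, seed: int = 0
) -> pd.DataFrame:
    """Random protein-protein association edge table with scores in [0, 1]."""
    rng = np.random.default_rng(seed)
    names = sorted(proteins)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if rng.random() < edge_prob:
                rows.append((a, b, round(float(rng.uniform(0.15, 0.999)), 3)))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def simulate_term_annotation(
    proteins: list[str],
    n_terms: int = 20,
    size_range: tuple[int, int] = (5, 25),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random term -> gene-set annotation over the given protein universe."""
    rng = np.random.default_rng(seed)
    names = sorted(proteins)
    lo, hi = size_range
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        k = min(int(rng.integers(lo, hi + 1)), len(names))
        members = rng.choice(names, size=k, replace=False)
        terms[f"TERM{t + 1:03d}"] = set(members.tolist())
    return terms


# ---------------------------------------------------------------------------
# Writers / readers (tab-delimited, UTF-8, header row, 1-based positions)

def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_positions": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ks_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ortholog_pairs(pairs: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(pairs.items()), columns=["source_id", "target_id"]
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_pairs(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["source_id"], df["target_id"]))


def write_position_maps(
    maps: dict[str, dict[int, int | None]], path: str | Path
) -> None:
    rows = [
        (pid, src, "deleted" if tgt is None else tgt)
        for pid in sorted(maps)
        for src, tgt in sorted(maps[pid].items())
    ]
    pd.DataFrame(rows, columns=["source_id", "source_pos", "target_pos"]).to_csv(
        path, sep="\t", index=False
    )


def read_position_maps(path: str | Path) -> dict[str, dict[int, int | None]]:
    df = pd.read_csv(path, sep="\t", dtype={"target_pos": str})
    maps: dict[str, dict[int, int | None]] = {}
    for pid, src, tgt in zip(df["source_id"], df["source_pos"], df["target_pos"]):
        maps.setdefault(pid, {})[int(src)] = None if tgt == "deleted" else int(tgt)
    return maps


def write_planted_deltas(
    planted: dict[str, dict[tuple[str, str], float]], path: str | Path
) -> None:
    rows = [
        (kin, cond, tp, d)
        for kin in sorted(planted)
        for (cond, tp), d in sorted(planted[kin].items())
    ]
    pd.DataFrame(
        rows, columns=["kinase", "condition", "timepoint", "delta"]
    ).to_csv(path, sep="\t", index=False)


def read_planted_deltas(path: str | Path) -> dict[str, dict[tuple[str, str], float]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[tuple[str, str], float]] = {}
    for kin, cond, tp, d in zip(
        df["kinase"], df["condition"], df["timepoint"], df["delta"]
    ):
        out.setdefault(kin, {})[(cond, str(tp))] = float(d)
    return out


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every input table the pipeline consumes plus the truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.tsv",
        "fasta_source": out / "source_proteins.faa",
        "fasta_target": out / "target_proteins.faa",
        "ortholog_pairs": out / "ortholog_pairs.tsv",
        "ks_annotation": out / "kinase_substrates_source.tsv",
        "ks_annotation_target": out / "kinase_substrates_target.tsv",
        "true_position_maps": out / "truth_position_maps.tsv",
        "planted_deltas": out / "truth_planted_deltas.tsv",
    }
    write_measurements(study.measurements, paths["measurements"])
    write_fasta(study.proteins, paths["fasta_source"])
    write_fasta(study.orthologs, paths["fasta_target"])
    write_ortholog_pairs(study.ortholog_pairs, paths["ortholog_pairs"])
    write_ks_annotation(study.ks_annotation, paths["ks_annotation"])
    write_ks_annotation(study.ks_annotation_target, paths["ks_annotation_target"])
    write_position_maps(study.truth.true_position_maps, paths["true_position_maps"])
    write_planted_deltas(study.truth.planted_kinase_deltas, paths["planted_deltas"])
    return paths
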