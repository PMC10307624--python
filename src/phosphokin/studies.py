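"""Validation studies: oracle comparisons and simulation-based calibration.

These studies quantify how well each stage behaves under controlled
conditions — alignment optimality against exhaustive enumeration,
phosphosite position-transfer recovery against the simulator's ground
truth, type-I calibration of the kinase z statistic under a null
simulation, and recovery of planted active kinases. They are shared by
the test suite and the reproduction script.

Study sizes (number of simulations, proteins per study) are fixed here as
the package's reference conditions; every study takes an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .kinase import annotation_from_frame, infer_activities
from .ortholog import AlignmentScoring, needleman_wunsch, transfer_site_position
from .quant import quantify
from .simulate import AMINO_ACIDS, SimulationDesign, generate_protein_set, mutate_ortholog, simulate_study

from Bio.Align import substitution_matrices


def brute_force_global_score(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Optimal global alignment score by exhaustive alignment enumeration.

    Recursively enumerates every global alignment (including insertion-
    adjacent-to-deletion paths), scoring gap runs as open + (L-1)*extend
    with end gaps penalized. Practical only for sequences of length <= ~8;
    serves as the independent optimality oracle for the aligner.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    mat = substitution_matrices.load(scoring.matrix)
    la, lb = len(seq_a), len(seq_b)
    best = -np.inf

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + mat[seq_a[i], seq_b[j]], "M")
        if i < la:
            g = scoring.gap_extend if last == "GB" else scoring.gap_open
            rec(i + 1, j, score + g, "GB")
        if j < lb:
            g = scoring.gap_extend if last == "GA" else scoring.gap_open
            rec(i, j + 1, score + g, "GA")

    rec(0, 0, 0.0, None)
    return float(best)


def alignment_oracle_agreement(
    n_pairs: int = 500, max_len: int = 6, seed: int = 0
) -> dict[str, float]:
    """Fraction of random short pairs where the aligner's score equals the
    exhaustive-enumeration optimum."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    agree = 0
    for _ in range(n_pairs):
        a = "".join(rng.choice(aa, size=int(rng.integers(1, max_len + 1))))
        b = "".join(rng.choice(aa, size=int(rng.integers(1, max_len + 1))))
        got = needleman_wunsch(a, b).score
        want = brute_force_global_score(a, b)
        agree += abs(got - want) < 1e-9
    return {"agreement_pct": 100.0 * agree / n_pairs, "n": n_pairs}


def transfer_recovery(
    n_proteins: int = 40,
    substitution_rate: float = 0.05,
    indel_rate: float = 0.02,
    seed: int = 0,
) -> dict[str, float]:
    """Phosphosite position-transfer accuracy on synthetic ortholog pairs.

    Mutates each protein into an ortholog with a recorded true position
    map, aligns the pair, and transfers every S/T/Y position that survived
    mutation. Returns the percentage of surviving sites whose transferred
    position equals the truth, plus the identity-pair sanity fraction.
    """
    proteins = generate_protein_set(n_proteins, (200, 400), seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_sites = n_correct = 0
    identity_ok = True
    for pid, seq in sorted(proteins.items()):
        ortholog, truth = mutate_ortholog(
            seq, substitution_rate, indel_rate, seed=int(rng.integers(2**31 - 1))
        )
        aln = needleman_wunsch(seq, ortholog)
        sites = [i + 1 for i, r in enumerate(seq) if r in "STY"]
        for pos in sites:
            if truth[pos] is None:
                continue
            n_sites += 1
            n_correct += transfer_site_position(aln, pos) == truth[pos]
        self_aln = needleman_wunsch(seq, seq)
        if any(transfer_site_position(self_aln, p) != p for p in sites[:5]):
            identity_ok = False
    return {
        "accuracy_pct": 100.0 * n_correct / n_sites,
        "n": n_sites,
        "identity_ok": float(identity_ok),
    }


def _calibration_design(seed: int) -> SimulationDesign:
    # one stimulation/timepoint pair per simulation keeps the studies fast;
    # the z statistic is computed per contrast, so this loses no generality
    return SimulationDesign(
        ligands=("fibrin",),
        timepoints=("1h",),
        n_replicates=3,
        n_proteins=120,
        sites_per_protein=(4, 5),
        noise_sd=0.3,
        seed=seed,
    )


def _simulate_activities(seed: int, n_active: int, delta: float):
    design = _calibration_design(seed)
    study = simulate_study(
        design,
        n_kinases=50,
        substrates_per_kinase=10,
        n_active=n_active,
        delta=delta,
        with_orthologs=False,
    )
    _, site_fc = quantify(study.measurements)
    annotation = annotation_from_frame(study.ks_annotation)
    acts = infer_activities(site_fc, annotation)
    return acts, set(study.truth.planted_kinase_deltas)


def null_calibration(n_sims: int = 200, seed: int = 0, alpha: float = 0.05) -> dict[str, float]:
    """Type-I calibration of the kinase z statistic under the null.

    Runs the full generator -> quant -> kinase-z chain with no planted
    kinase shifts; reports the fraction of (kinase, contrast) tests with
    two-tailed p < alpha and a Kolmogorov-Smirnov p value of the pooled z
    values (all kinases have >= 10 measured substrates by design) against
    the standard normal.
    """
    rng = np.random.default_rng(seed)
    n_sig = n_tests = 0
    zs: list[np.ndarray] = []
    for _ in range(n_sims):
        acts, _ = _simulate_activities(int(rng.integers(2**31 - 1)), n_active=0, delta=0.0)
        n_tests += len(acts)
        n_sig += int((acts["p"] < alpha).sum())
        zs.append(acts.loc[acts["m"] >= 10, "z"].to_numpy())
    z_all = np.concatenate(zs)
    ks = stats.kstest(z_all, "norm")
    return {
        "significant_fraction": n_sig / n_tests,
        "n_tests": n_tests,
        "ks_p": float(ks.pvalue),
        "n_z": int(z_all.size),
    }


def planted_recovery(
    n_sims: int = 100, n_active: int = 5, delta: float = 1.5, seed: int = 0
) -> dict[str, float]:
    """Recovery of planted active kinases by |z| ranking.

    Plants ``n_active`` kinases with a log2FC shift of ``delta`` on their
    substrates (out of 50 annotated kinases) and reports in what
    percentage of simulations the planted kinases occupy exactly the top
    ``n_active`` |z| ranks.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        acts, planted = _simulate_activities(
            int(rng.integers(2**31 - 1)), n_active=n_active, delta=delta
        )
        top = set(
            acts.assign(abs_z=acts["z"].abs())
            .sort_values("abs_z", ascending=False)
            .head(n_active)["kinase"]
        )
        hits += top == planted
    return {"top_rank_recovery_pct": 100.0 * hits / n_sims, "n": n_sims}
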