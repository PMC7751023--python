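"""Linking structural covariance networks to cognition.

Two behavioural PLS models, mirroring the cross-sectional and longitudinal
arms of the analysis:

1. cross-sectional — sub-acute SCN scores (confound-residualized brain
   scores of the 12 single-seed PLS models) against the residualized
   17-test battery;
2. longitudinal — change SCN scores (from chronic-minus-sub-acute GM maps,
   with scan interval added to the confound design) against residualized
   test-change scores.

Both produce the same report: per-LV permutation p and variance explained,
the latent brain-behaviour correlation with its permutation p, per-test
correlations with bootstrap 95% CIs, per-seed bootstrap ratios and the
|BSR| >= 2 contributor list.  A split-half validation re-runs the entire
model independently in random disjoint halves of the cohort.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .battery import (
    CognitiveBattery,
    ConfoundTable,
    confound_design as _confound_design,
    impute_battery,
    residualize,
)
from .exceptions import AlignmentError, ConfigurationError, DataError
from .gm_maps import GMDataset, SeedSpec, compute_change_dataset, extract_seed_means
from .pls import (
    BSR_CONTRIBUTION_THRESHOLD,
    PLSCorrelation,
    PLSResult,
    derive_scn,
)


@dataclasses.dataclass
class SCNScores:
    """Subjects x seeds table of confound-residualized brain scores."""

    subject_ids: list[str]
    seed_names: list[str]
    values: np.ndarray
    epoch: str  # 'subacute' or 'change'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.seed_names)):
            raise DataError("SCN score shape mismatch")


def build_scn_scores(
    gm: GMDataset,
    seeds: Sequence[SeedSpec],
    confounds: ConfoundTable,
    epoch: str = "subacute",
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    confound_columns: Sequence[str] | None = None,
) -> tuple[SCNScores, dict[str, PLSResult]]:
    """One single-seed PLS per seed; residualized LV1 brain scores.

    ``epoch='change'`` expects ``gm`` to be a change dataset and appends the
    scan interval to the confound design.
    """
    if epoch not in ("subacute", "change"):
        raise ConfigurationError(f"unknown epoch {epoch!r}")
    include_interval = epoch == "change"
    if include_interval and "scan_interval" not in confounds.frame.columns:
        raise ConfigurationError(
            "epoch='change' requires a scan_interval confound column"
        )
    if gm.subject_ids != confounds.subject_ids:
        raise AlignmentError("GM and confound subjects differ")
    seed_means = extract_seed_means(gm, seeds)
    results: dict[str, PLSResult] = {}
    brain_scores = np.empty((gm.n_subjects, len(seeds)))
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(seeds))
    for s, seed in enumerate(seeds):
        res = derive_scn(
            gm,
            seed_means.values[:, [s]],
            n_perm=n_perm,
            n_boot=n_boot,
            rng_seed=int(np.random.default_rng(children[s]).integers(2**31)),
            scaling="covariance",
        )
        results[seed.name] = res
        brain_scores[:, s] = res.left_scores[:, 0]
    resid = residualize(
        brain_scores,
        confounds,
        include_scan_interval=include_interval,
        columns=confound_columns,
    )
    scores = SCNScores(
        subject_ids=list(gm.subject_ids),
        seed_names=[s.name for s in seeds],
        values=resid,
        epoch=epoch,
    )
    return scores, results


def derive_network_maps(
    gm: GMDataset,
    seeds: Sequence[SeedSpec],
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
) -> dict[str, PLSResult]:
    """One seed PLS per network from its 2-seed block (salience/BSR maps)."""
    seed_means = extract_seed_means(gm, seeds)
    networks: dict[str, list[int]] = {}
    for idx, s in enumerate(seeds):
        networks.setdefault(s.network, []).append(idx)
    out: dict[str, PLSResult] = {}
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(networks))
    for child, (net, cols) in zip(children, networks.items()):
        out[net] = derive_scn(
            gm,
            seed_means.values[:, cols],
            n_perm=n_perm,
            n_boot=n_boot,
            rng_seed=int(np.random.default_rng(child).integers(2**31)),
            scaling="covariance",
        )
    return out


def _report_from_result(
    res: PLSResult, test_names: Sequence[str], seed_names: Sequence[str]
) -> dict:
    """JSON-friendly model report (LV stats, loadings, contributors)."""
    report: dict = {
        "n_lv": res.n_lv,
        "singular_values": res.singular_values.tolist(),
        "variance_explained": res.variance_explained.tolist(),
        "perm_p": None if res.perm_p is None else res.perm_p.tolist(),
        "latent_r": None if res.latent_r is None else res.latent_r.tolist(),
        "latent_r_perm_p": (
            None if res.latent_r_perm_p is None else res.latent_r_perm_p.tolist()
        ),
        "n_infinite_bsr": res.n_infinite_bsr,
    }
    lv = 0
    tests = []
    for j, t in enumerate(test_names):
        entry = {"test": t, "salience": float(res.right_saliences[j, lv])}
        if res.right_loading_ci is not None:
            lo, hi = res.right_loading_ci[j, lv]
            entry["loading_ci"] = [float(lo), float(hi)]
        if res.right_bootstrap_ratios is not None:
            entry["bsr"] = float(res.right_bootstrap_ratios[j, lv])
        tests.append(entry)
    report["tests_lv1"] = tests
    seeds_out = []
    for j, s in enumerate(seed_names):
        entry = {"seed": s, "salience": float(res.left_saliences[j, lv])}
        if res.left_bootstrap_ratios is not None:
            entry["bsr"] = float(res.left_bootstrap_ratios[j, lv])
        seeds_out.append(entry)
    report["seeds_lv1"] = seeds_out
    if res.left_bootstrap_ratios is not None:
        report["contributing_seeds_lv1"] = [
            s
            for j, s in enumerate(seed_names)
            if abs(res.left_bootstrap_ratios[j, 0]) >= BSR_CONTRIBUTION_THRESHOLD
        ]
    if res.right_bootstrap_ratios is not None:
        report["contributing_tests_lv1"] = [
            t
            for j, t in enumerate(test_names)
            if abs(res.right_bootstrap_ratios[j, 0]) >= BSR_CONTRIBUTION_THRESHOLD
        ]
    return report


def behavioural_pls(
    battery_resid: np.ndarray,
    scn: SCNScores,
    test_names: Sequence[str] | None = None,
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    scaling: str = "correlation",
    confound_design: np.ndarray | None = None,
) -> tuple[PLSResult, dict]:
    """Behavioural PLS of residualized test scores against SCN scores.

    X is the brain block (SCN scores), Y the behavioural block, so LV1's
    left scores are subject "brain scores" and right scores "behavioural
    scores"; per-test loadings are correlations with the brain score.

    When the nuisance design that produced the residuals is supplied, it
    is handed to the engine so permutations re-residualize the permuted
    battery rather than shuffling residual rows (residualizing once is
    idempotent, so passing already-residualized blocks stays correct).
    """
    Y = np.asarray(battery_resid, dtype=float)
    if Y.ndim != 2:
        raise DataError("battery block must be 2D")
    if Y.shape[0] != len(scn.subject_ids):
        raise AlignmentError("battery and SCN blocks have different subjects")
    if np.isnan(Y).any():
        raise DataError("battery block contains missing values; impute first")
    if test_names is None:
        test_names = [f"test_{j + 1}" for j in range(Y.shape[1])]
    est = PLSCorrelation(
        scaling=scaling, n_perm=n_perm, n_boot=n_boot, random_state=rng_seed,
        confounds=confound_design,
    )
    res = est.fit(scn.values, Y).result()
    report = _report_from_result(res, test_names, scn.seed_names)
    report["epoch"] = scn.epoch
    return res, report


def longitudinal_model(
    subacute_gm: GMDataset,
    chronic_gm: GMDataset,
    battery_subacute: CognitiveBattery,
    battery_chronic: CognitiveBattery,
    confounds: ConfoundTable,
    seeds: Sequence[SeedSpec],
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    confound_columns: Sequence[str] | None = None,
    imputation_components: int = 2,
) -> tuple[PLSResult, dict]:
    """Change SCN scores vs residualized test-change scores.

    Each timepoint's battery is imputed separately first; change scores are
    chronic minus sub-acute, residualized with scan interval included.
    """
    if battery_subacute.subject_ids != battery_chronic.subject_ids:
        raise AlignmentError("battery timepoints cover different subjects")
    change_gm = compute_change_dataset(subacute_gm, chronic_gm)
    if np.allclose(change_gm.data, 0.0):
        raise DataError("chronic GM equals sub-acute GM; change model is degenerate")
    ss = np.random.SeedSequence(rng_seed)
    scn_ss, pls_ss = ss.spawn(2)
    scn, seed_results = build_scn_scores(
        change_gm,
        seeds,
        confounds,
        epoch="change",
        rng_seed=int(np.random.default_rng(scn_ss).integers(2**31)),
        confound_columns=confound_columns,
    )
    b_sub, _ = impute_battery(battery_subacute, n_components=imputation_components)
    b_chr, _ = impute_battery(battery_chronic, n_components=imputation_components)
    change_scores = b_chr.scores - b_sub.scores
    if np.allclose(change_scores, 0.0):
        raise DataError("test scores are identical at both timepoints")
    resid = residualize(
        change_scores, confounds, include_scan_interval=True, columns=confound_columns
    )
    res, report = behavioural_pls(
        resid,
        scn,
        test_names=battery_subacute.test_names,
        n_perm=n_perm,
        n_boot=n_boot,
        rng_seed=int(np.random.default_rng(pls_ss).integers(2**31)),
        confound_design=_confound_design(confounds, True, confound_columns),
    )
    report["model"] = "longitudinal"
    return res, report


def cross_sectional_model(
    gm: GMDataset,
    battery: CognitiveBattery,
    confounds: ConfoundTable,
    seeds: Sequence[SeedSpec],
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    confound_columns: Sequence[str] | None = None,
    imputation_components: int = 2,
) -> tuple[PLSResult, dict]:
    """Sub-acute SCN scores vs residualized sub-acute battery."""
    ss = np.random.SeedSequence(rng_seed)
    scn_ss, pls_ss = ss.spawn(2)
    scn, _ = build_scn_scores(
        gm,
        seeds,
        confounds,
        epoch="subacute",
        rng_seed=int(np.random.default_rng(scn_ss).integers(2**31)),
        confound_columns=confound_columns,
    )
    b, _ = impute_battery(battery, n_components=imputation_components)
    resid = residualize(
        b.scores, confounds, include_scan_interval=False, columns=confound_columns
    )
    res, report = behavioural_pls(
        resid,
        scn,
        test_names=battery.test_names,
        n_perm=n_perm,
        n_boot=n_boot,
        rng_seed=int(np.random.default_rng(pls_ss).integers(2**31)),
        confound_design=_confound_design(confounds, False, confound_columns),
    )
    report["model"] = "cross_sectional"
    return res, report


def _subset_battery(battery: CognitiveBattery, idx: np.ndarray) -> CognitiveBattery:
    return CognitiveBattery(
        subject_ids=[battery.subject_ids[i] for i in idx],
        test_names=list(battery.test_names),
        scores=battery.scores[idx],
        domain=dict(battery.domain),
        direction=dict(battery.direction),
    )


def _subset_gm(gm: GMDataset, idx: np.ndarray) -> GMDataset:
    return GMDataset(
        subject_ids=[gm.subject_ids[i] for i in idx],
        data=gm.data[idx],
        mask=gm.mask,
        affine=gm.affine,
        timepoint=gm.timepoint,
    )


def _subset_confounds(conf: ConfoundTable, idx: np.ndarray) -> ConfoundTable:
    return ConfoundTable(
        subject_ids=[conf.subject_ids[i] for i in idx],
        frame=conf.frame.iloc[idx],
    )


def split_half_validation(
    subacute_gm: GMDataset,
    battery_subacute: CognitiveBattery,
    confounds: ConfoundTable,
    seeds: Sequence[SeedSpec],
    chronic_gm: GMDataset | None = None,
    battery_chronic: CognitiveBattery | None = None,
    mode: str = "cross_sectional",
    n_repeats: int = 5,
    n_perm: int = 0,
    n_boot: int = 0,
    rng_seed: int | None = None,
    confound_columns: Sequence[str] | None = None,
) -> list[dict]:
    """Refit the full model in random disjoint halves, ``n_repeats`` times.

    Every repeat partitions the cohort into two halves (sizes differing by
    at most one) covering all subjects, and reruns SCN-score derivation and
    behavioural PLS independently within each half.  Returns
    ``2 * n_repeats`` reports; each also carries a cross-half LV1 salience
    correlation as an extra stability diagnostic.
    """
    n = subacute_gm.n_subjects
    if n < 20:
        raise DataError("split-half validation needs at least 20 subjects")
    if mode == "longitudinal" and (chronic_gm is None or battery_chronic is None):
        raise ConfigurationError("longitudinal split-half needs chronic inputs")
    rng = np.random.default_rng(rng_seed)
    reports: list[dict] = []
    for rep in range(n_repeats):
        order = rng.permutation(n)
        halves = (np.sort(order[: n // 2]), np.sort(order[n // 2 :]))
        half_results = []
        for h, idx in enumerate(halves):
            sub_gm = _subset_gm(subacute_gm, idx)
            sub_bat = _subset_battery(battery_subacute, idx)
            sub_conf = _subset_confounds(confounds, idx)
            seed = int(rng.integers(2**31))
            if mode == "cross_sectional":
                res, rep_dict = cross_sectional_model(
                    sub_gm, sub_bat, sub_conf, seeds,
                    n_perm=n_perm, n_boot=n_boot, rng_seed=seed,
                    confound_columns=confound_columns,
                )
            else:
                res, rep_dict = longitudinal_model(
                    sub_gm,
                    _subset_gm(chronic_gm, idx),
                    sub_bat,
                    _subset_battery(battery_chronic, idx),
                    sub_conf,
                    seeds,
                    n_perm=n_perm, n_boot=n_boot, rng_seed=seed,
                    confound_columns=confound_columns,
                )
            rep_dict.update(repeat=rep, half=h, n_subjects=int(len(idx)))
            half_results.append((res, rep_dict))
        # stability diagnostic (not part of the published procedure): LV1
        # salience agreement across halves after sign alignment
        a = np.concatenate([
            half_results[0][0].left_saliences[:, 0],
            half_results[0][0].right_saliences[:, 0],
        ])
        b = np.concatenate([
            half_results[1][0].left_saliences[:, 0],
            half_results[1][0].right_saliences[:, 0],
        ])
        if a @ b < 0:
            b = -b
        cosine = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        agreement = float(np.mean(np.sign(a) == np.sign(b)))
        for _, rep_dict in half_results:
            rep_dict["cross_half_salience_cosine"] = cosine
            rep_dict["cross_half_sign_agreement"] = agreement
            reports.append(rep_dict)
    return reports
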