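"""Run orchestration: configuration, disk I/O, manifests, reports.

A run configuration is a YAML file; a run directory holds the report JSON,
score tables (TSV), salience/BSR maps (NIfTI) and a manifest recording the
config snapshot, per-stage seeds, software version, input checksums and
timing — enough to reproduce the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import DEFAULT_TESTS, CognitiveBattery, ConfoundTable
from .behaviour import (
    cross_sectional_model,
    derive_network_maps,
    longitudinal_model,
    split_half_validation,
)
from .exceptions import ConfigurationError, DataError
from .gm_maps import GMDataset, load_gm_dataset, read_seed_table
from .simulate import Cohort, CohortConfig, generate_cohort, write_cohort

_COHORT_FIELDS = {f.name for f in dataclasses.fields(CohortConfig)}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see ``example_config``)."""

    data_dir: str | None = None
    out_dir: str = "run"
    n_perm: int = 200
    n_boot: int = 100
    n_repeats: int = 5
    rng_seed: int = 0
    mask_threshold: float = 0.45
    confound_columns: list[str] | None = None
    full_scale: bool = False
    write_maps: bool = True
    cohort: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.full_scale:
            self.n_perm, self.n_boot = 5000, 1000
        bad = set(self.cohort) - _COHORT_FIELDS
        if bad:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        return CohortConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(config: RunConfig, stage_seeds: dict, outputs: dict,
              checksums: dict, t0: float) -> dict:
    return {
        "software": {"name": "scnpls", "version": __version__},
        "config": dataclasses.asdict(config),
        "stage_seeds": stage_seeds,
        "input_checksums": checksums,
        "outputs": outputs,
        "elapsed_s": round(time.monotonic() - t0, 3),
    }


def load_cohort_dir(data_dir: str | Path, mask_threshold: float = 0.45) -> Cohort:
    """Read a cohort from a directory written by ``cmd_simulate``.

    Expects ``subacute/`` (and optionally ``chronic/``) NIfTI volumes,
    ``battery_*.tsv``, ``battery_meta.tsv``, ``confounds.tsv``, ``seeds.tsv``.
    """
    d = Path(data_dir)
    if not d.is_dir():
        raise DataError(f"data directory {d} does not exist")

    def _gm(sub: str, timepoint: str) -> GMDataset:
        paths = sorted((d / sub).glob("gm_sub-*.nii*"))
        if not paths:
            raise DataError(f"no GM volumes under {d / sub}")
        ids = [p.name.replace("gm_", "").split(".")[0] for p in paths]
        return load_gm_dataset(
            paths, mask_threshold=mask_threshold, subject_ids=ids, timepoint=timepoint
        )

    subacute = _gm("subacute", "subacute")
    chronic = None
    if (d / "chronic").is_dir():
        chronic = _gm("chronic", "chronic")
        shared = subacute.mask & chronic.mask
        sub_v = subacute.to_volumes()[:, shared]
        chr_v = chronic.to_volumes()[:, shared]
        subacute = GMDataset(subacute.subject_ids, sub_v, shared,
                             subacute.affine, "subacute")
        chronic = GMDataset(chronic.subject_ids, chr_v, shared,
                            chronic.affine, "chronic")

    meta = pd.read_csv(d / "battery_meta.tsv", sep="\t")
    domain = dict(zip(meta["test"], meta["domain"]))
    direction = dict(zip(meta["test"], meta["direction"]))

    def _battery(name: str) -> CognitiveBattery | None:
        p = d / f"battery_{name}.tsv"
        if not p.exists():
            return None
        frame = pd.read_csv(p, sep="\t", index_col=0)
        return CognitiveBattery.from_frame(frame, domain, direction)

    conf = pd.read_csv(d / "confounds.tsv", sep="\t", index_col=0)
    confounds = ConfoundTable([str(i) for i in conf.index], conf)
    seeds = read_seed_table(d / "seeds.tsv")
    return Cohort(
        subacute=subacute,
        chronic=chronic,
        battery_subacute=_battery("subacute"),
        battery_chronic=_battery("chronic"),
        confounds=confounds,
        lesion_masks=np.zeros((subacute.n_subjects,) + subacute.mask.shape, bool),
        seeds=seeds,
        truth=None,
        config=None,
    )


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic cohort, write it and a manifest; returns manifest."""
    t0 = time.monotonic()
    out = Path(out_dir)
    cohort = generate_cohort(config.cohort_config(), rng_seed=config.rng_seed)
    index = write_cohort(cohort, out)
    checksums = {}
    for key in ("battery_subacute", "battery_chronic", "confounds", "seeds"):
        if key in index:
            checksums[key] = _sha256(Path(index[key]))
    manifest = _manifest(
        config, {"generate_cohort": config.rng_seed}, index, checksums, t0
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_model(
    cohort: Cohort,
    config: RunConfig,
    mode: str,
) -> tuple[dict | list, dict]:
    """Execute one analysis mode on an in-memory cohort.

    Returns (report, stage_seeds).  Modes: ``cross_sectional``,
    ``longitudinal``, ``split_half``.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    model_seed = int(np.random.default_rng(ss).integers(2**31))
    stage_seeds = {"model": model_seed}
    if mode == "cross_sectional":
        _, report = cross_sectional_model(
            cohort.subacute,
            cohort.battery_subacute,
            cohort.confounds,
            cohort.seeds,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            rng_seed=model_seed,
            confound_columns=config.confound_columns,
        )
        return report, stage_seeds
    if mode == "longitudinal":
        if cohort.chronic is None or cohort.battery_chronic is None:
            raise ConfigurationError("longitudinal mode requires chronic inputs")
        _, report = longitudinal_model(
            cohort.subacute,
            cohort.chronic,
            cohort.battery_subacute,
            cohort.battery_chronic,
            cohort.confounds,
            cohort.seeds,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            rng_seed=model_seed,
            confound_columns=config.confound_columns,
        )
        return report, stage_seeds
    if mode == "split_half":
        reports = split_half_validation(
            cohort.subacute,
            cohort.battery_subacute,
            cohort.confounds,
            cohort.seeds,
            chronic_gm=cohort.chronic,
            battery_chronic=cohort.battery_chronic,
            mode="longitudinal" if cohort.chronic is not None else "cross_sectional",
            n_repeats=config.n_repeats,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            rng_seed=model_seed,
            confound_columns=config.confound_columns,
        )
        return reports, stage_seeds
    raise ConfigurationError(f"unknown mode {mode!r}")


def cmd_fit(config: RunConfig, mode: str, out_dir: str | Path) -> dict:
    """Load (or generate) inputs, run one mode, write report + maps + manifest."""
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    if config.data_dir is not None:
        cohort = load_cohort_dir(config.data_dir, config.mask_threshold)
        for name in ("battery_subacute.tsv", "confounds.tsv", "seeds.tsv"):
            p = Path(config.data_dir) / name
            if p.exists():
                checksums[name] = _sha256(p)
    else:
        cohort = generate_cohort(config.cohort_config(), rng_seed=config.rng_seed)
    report, stage_seeds = run_model(cohort, config, mode)
    outputs: dict[str, Any] = {}
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    outputs["report"] = str(report_path)

    if mode != "split_half" and config.write_maps:
        net_seed = int(np.random.default_rng(
            np.random.SeedSequence(config.rng_seed).spawn(2)[1]
        ).integers(2**31))
        stage_seeds["network_maps"] = net_seed
        gm = cohort.subacute
        if mode == "longitudinal":
            from .gm_maps import compute_change_dataset

            gm = compute_change_dataset(cohort.subacute, cohort.chronic)
        nets = derive_network_maps(
            gm, cohort.seeds, n_boot=config.n_boot, rng_seed=net_seed
        )
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        for net, res in nets.items():
            sal = gm.unmask(res.left_saliences[:, 0])
            nib.save(nib.Nifti1Image(sal, gm.affine),
                     str(map_dir / f"salience_{net}.nii.gz"))
            if res.left_bootstrap_ratios is not None:
                bsr = res.left_bootstrap_ratios[:, 0]
                bsr = np.where(np.isfinite(bsr), bsr, 0.0)
                nib.save(nib.Nifti1Image(gm.unmask(bsr), gm.affine),
                         str(map_dir / f"bsr_{net}.nii.gz"))
        outputs["maps"] = str(map_dir)

    manifest = _manifest(config, stage_seeds, outputs, checksums, t0)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def cmd_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run = Path(run_dir)
    report_path = run / "report.json"
    if not report_path.exists():
        raise DataError(f"{run} has no report.json (incomplete run?)")
    with open(report_path) as fh:
        report = json.load(fh)
    lines: list[str] = []
    reports = report if isinstance(report, list) else [report]
    for rep in reports:
        label = rep.get("model", "model")
        if "repeat" in rep:
            label += f" repeat {rep['repeat']} half {rep['half']} (n={rep['n_subjects']})"
        lines.append(f"== {label} ==")
        ve = rep["variance_explained"][0] * 100
        lines.append(f"LV1 variance explained: {ve:.2f}%")
        if rep.get("perm_p"):
            lines.append(f"LV1 permutation p: {rep['perm_p'][0]:.4g}")
        if rep.get("latent_r"):
            lines.append(f"LV1 latent r: {rep['latent_r'][0]:.3f}")
        lines.append(f"SCN seeds: {len(rep['seeds_lv1'])}; tests: {len(rep['tests_lv1'])}")
        if rep.get("contributing_seeds_lv1") is not None:
            lines.append(
                "contributing seeds (|BSR|>=2): "
                + (", ".join(rep["contributing_seeds_lv1"]) or "none")
            )
        if rep.get("n_infinite_bsr"):
            lines.append(f"WARNING: {rep['n_infinite_bsr']} infinite bootstrap ratios")
        lines.append("")
        # figure-ready tables
        pd.DataFrame(rep["tests_lv1"]).to_csv(
            run / f"tests_lv1{'_r%d_h%d' % (rep['repeat'], rep['half']) if 'repeat' in rep else ''}.tsv",
            sep="\t", index=False,
        )
        pd.DataFrame(rep["seeds_lv1"]).to_csv(
            run / f"seeds_lv1{'_r%d_h%d' % (rep['repeat'], rep['half']) if 'repeat' in rep else ''}.tsv",
            sep="\t", index=False,
        )
    return "\n".join(lines)


def example_config() -> str:
    """A commented example YAML run configuration."""
    return (
        "# scnpls run configuration\n"
        "# data_dir: null  # omit to simulate a cohort on the fly\n"
        "out_dir: run\n"
        "n_perm: 200      # 5000 at full inference scale\n"
        "n_boot: 100      # 1000 at full inference scale\n"
        "n_repeats: 5     # split-half repeats\n"
        "rng_seed: 0\n"
        "mask_threshold: 0.45\n"
        "# confound_columns: [age, sex, handedness, log_infarct_volume, tiv]\n"
        "full_scale: false\n"
        "write_maps: true\n"
        "cohort:\n"
        "  n_subjects: 73\n"
        "  latent_r: 0.3\n"
    )
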