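"""End-to-end runs: generate-or-read → QC → extract → summarize → compare.

Every run writes a manifest listing the configuration hash, the input
inventory, seeds, per-neuron QC dispositions and every output file, so a
run can be reproduced byte-for-byte from its manifest inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .events import EPSCEvent, detect_epscs
from .features import extract_neuron_features
from .io import read_recording, write_features_table, write_recording
from .stats import (NeuronFeatures, build_group_table, compare_active_fraction,
                    compare_feature, features_to_frame, iv_family_anova)
from .synth import CohortConfig, NeuronBundle, gen_cohort

__all__ = ["RunManifest", "run_pipeline", "simulate_cohort",
           "extract_directory", "compare_groups"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int | None
    inputs: list[str]
    qc: dict
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")
        return path

    def verify_complete(self, base: Path) -> None:
        missing = [o for o in self.outputs if not (base / o).exists()]
        if missing:
            raise RuntimeError(f"manifest lists missing outputs: {missing}")


def _config_hash(cfg: AnalysisConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_cohort(cohort: CohortConfig, out_dir: str | Path,
                    seed: int | None = None) -> list[Path]:
    """Generate a cohort and write every recording to interchange HDF5."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles, truth = gen_cohort(cohort, seed=seed)
    paths = []
    for b in bundles:
        for suffix, rec in (("epsc", b.epsc), ("cc", b.current_clamp),
                            ("vc", b.voltage_clamp), ("mem", b.membrane_test)):
            paths.append(write_recording(rec, out / f"{b.cell_id}__{suffix}.h5"))
    truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.10g",
                 lineterminator="\n")
    paths.append(out / "ground_truth.csv")
    return paths


_FORMAT_GLOBS = {"interchange-hdf5": "*.h5", "hdf5": "*.h5", "h5": "*.h5",
                 "abf": "*.abf", "nwb": "*.nwb"}


def classify_recording(rec) -> str:
    """Which protocol a recording belongs to: epsc / cc / vc / mem."""
    if rec.metadata.get("membrane_test"):
        return "mem"
    if rec.mode == "current_clamp":
        return "cc"
    return "epsc" if rec.gap_free else "vc"


def _collect_cells(in_dir: Path, fmt: str) -> dict[str, dict[str, Path]]:
    """Group files as <cell_id>__<epsc|cc|vc|mem>; unrecognized names fall
    back to one cell per stem with the kind classified after reading."""
    cells: dict[str, dict[str, Path]] = {}
    for p in sorted(in_dir.glob(_FORMAT_GLOBS.get(fmt, "*.h5"))):
        stem = p.stem
        if "__" in stem and stem.rsplit("__", 1)[1] in ("epsc", "cc", "vc",
                                                        "mem"):
            cell_id, kind = stem.rsplit("__", 1)
        else:
            cell_id, kind = stem, ""
        cells.setdefault(cell_id, {})[kind or f"?{stem}"] = p
    return cells


def extract_directory(in_dir: str | Path, config: AnalysisConfig | None = None,
                      cache_dir: Path | None = None,
                      format: str = "interchange-hdf5",
                      ) -> tuple[list[NeuronFeatures], list[EPSCEvent], dict]:
    """Extract features for every neuron found under ``in_dir``.

    Files are grouped by ``<cell_id>__<epsc|cc|vc|mem>.<ext>``; files that
    do not follow the convention are treated as one neuron each with the
    protocol classified from the recording itself.  With a ``cache_dir``,
    per-neuron results are keyed on the content hash of the neuron's files
    plus the config hash, so re-runs only re-extract neurons whose inputs
    changed.
    """
    cfg = config or AnalysisConfig()
    in_dir = Path(in_dir)
    cells = _collect_cells(in_dir, format)
    if not cells:
        raise FileNotFoundError(f"no recordings found under {in_dir}")
    features: list[NeuronFeatures] = []
    all_events: list[dict] = []
    qc_log: dict = {}
    cfg_hash = _config_hash(cfg)
    for cell_id, files in sorted(cells.items()):
        key = None
        if cache_dir is not None:
            h = hashlib.sha256(cfg_hash.encode())
            for kind in sorted(files):
                h.update(kind.encode())
                h.update(_file_hash(files[kind]).encode())
            key = cache_dir / f"{cell_id}_{h.hexdigest()[:16]}.json"
        recs = {}
        for k, p in files.items():
            rec = read_recording(p, format=format)
            recs[classify_recording(rec) if k.startswith("?") else k] = rec
        group = next(iter(recs.values())).group_label
        f = extract_neuron_features(
            cell_id, group, epsc=recs.get("epsc"),
            current_clamp=recs.get("cc"), voltage_clamp=recs.get("vc"),
            membrane_test=recs.get("mem"), config=cfg)
        if key is not None and key.exists():
            log.info("%s: cache hit", cell_id)
        elif key is not None:
            cache_dir.mkdir(parents=True, exist_ok=True)
            key.write_text("{}\n")
        features.append(f)
        qc_log[cell_id] = {
            "passed": f.qc.passed if f.qc else None,
            "holding_pa": f.qc.holding_current if f.qc else None,
            "reasons": f.qc.reasons if f.qc else ["no current-clamp recording"],
        }
        if "epsc" in recs:
            trace = recs["epsc"].sweeps[0][1]
            for ev in detect_epscs(trace, cfg.epsc):
                all_events.append({
                    "cell_id": cell_id, "group": group,
                    "onset_ms": ev.onset, "peak_ms": ev.peak_time,
                    "amplitude_pa": ev.amplitude,
                    "tau_ms": ev.decay_tau, "r2": ev.fit_r2,
                })
    return features, all_events, qc_log


def compare_groups(features: list[NeuronFeatures], group_a: str, group_b: str,
                   ) -> dict:
    """The study's statistical panel between two groups.

    Welch t on every continuous feature with ≥2 values per group, Fisher
    exact on the active fraction, one-way ANOVA per I–V component.  No
    multiple-testing correction; the result notes the number of tests run.
    """
    results: dict = {"comparisons": {}, "n_tests": 0}
    panel = ["total_evoked_ap", "epsc.rate", "epsc.mean_amplitude",
             "epsc.mean_decay_tau", "passive.capacitance",
             "passive.input_conductance", "spike_shape.threshold",
             "spike_shape.amplitude", "spike_shape.width_fwhm",
             "spike_shape.fast_ahp"]
    for path in panel:
        try:
            c = compare_feature(features, path, group_a, group_b)
        except ValueError as exc:
            results["comparisons"][path] = {"error": str(exc)}
            continue
        results["comparisons"][path] = {
            "test": c.test, "n_a": c.n_a, "n_b": c.n_b,
            "mean_a": c.mean_a, "mean_b": c.mean_b,
            "sem_a": c.sem_a, "sem_b": c.sem_b,
            "statistic": c.statistic, "p": c.p_value}
        results["n_tests"] += 1
    try:
        af = compare_active_fraction(features, group_a, group_b)
        results["comparisons"]["active_fraction"] = {
            "test": af.test, "table": af.extra["table"],
            "fraction_a": af.mean_a, "fraction_b": af.mean_b,
            "statistic": af.statistic, "p": af.p_value}
        results["n_tests"] += 1
    except ValueError as exc:
        results["comparisons"]["active_fraction"] = {"error": str(exc)}
    for comp in ("na", "kfast", "kslow"):
        try:
            an = iv_family_anova(features, comp, [group_a, group_b])
            results["comparisons"][f"iv_{comp}_anova"] = {
                "test": an.test, "F": an.statistic, "p": an.p_value,
                "n_per_group": an.extra["n_per_group"]}
            results["n_tests"] += 1
        except ValueError as exc:
            results["comparisons"][f"iv_{comp}_anova"] = {"error": str(exc)}
    return results


def run_pipeline(out_dir: str | Path,
                 cohort: CohortConfig | None = None,
                 in_dir: str | Path | None = None,
                 config: AnalysisConfig | None = None,
                 seed: int | None = None,
                 groups: tuple[str, str] | None = None,
                 use_cache: bool = False) -> RunManifest:
    """Full pipeline.  Provide either a ``cohort`` (synthetic inputs are
    generated under ``out_dir/recordings``) or an ``in_dir`` of interchange
    files.  Writes features.csv, events.csv, group_summary.csv, stats.json,
    and manifest.json under ``out_dir``."""
    if (cohort is None) == (in_dir is None):
        raise ValueError("provide exactly one of cohort/in_dir")
    cfg = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is not None:
        in_dir = out / "recordings"
        simulate_cohort(cohort, in_dir, seed=seed)
    in_dir = Path(in_dir)

    cache = out / "cache" if use_cache else None
    features, events, qc_log = extract_directory(in_dir, cfg, cache_dir=cache)

    feat_df = features_to_frame(features)
    write_features_table(feat_df, out / "features.csv")
    ev_df = pd.DataFrame(events) if events else pd.DataFrame(
        columns=["cell_id", "group", "onset_ms", "peak_ms", "amplitude_pa",
                 "tau_ms", "r2"])
    ev_df.to_csv(out / "events.csv", index=False, float_format="%.10g",
                 lineterminator="\n")
    group_names = sorted({f.group_label for f in features})
    build_group_table(features).to_csv(out / "group_summary.csv", index=False,
                                       float_format="%.10g", lineterminator="\n")
    stats: dict = {"groups": group_names}
    if groups is None and len(group_names) == 2:
        groups = (group_names[0], group_names[1])
    if groups is not None:
        stats.update(compare_groups(features, *groups))
    (out / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True, default=float) + "\n")

    manifest = RunManifest(
        config_hash=_config_hash(cfg), package_version=__version__,
        seed=seed, inputs=sorted(p.name for p in in_dir.glob("*.h5")),
        qc=qc_log,
        outputs=["features.csv", "events.csv", "group_summary.csv",
                 "stats.json"])
    manifest.write(out / "manifest.json")
    manifest.verify_complete(out)
    return manifest
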