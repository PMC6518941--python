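"""End-to-end orchestration: config, staged execution, provenance.

A :class:`PipelineConfig` (loadable from JSON) drives the chain
synthetic/loaded genotypes -> genotype+site filters -> windowed scan ->
inversion karyotyping + bootstrap tests, and synthetic/loaded detections ->
cleaning -> COA -> monthly traits.  Each stage writes its artefact plus a
provenance JSON (inputs, parameters, seed) into the output directory;
stages are cached on a content hash of their inputs and parameters, so
deleting one intermediate and rerunning regenerates only the downstream
stages.  No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gio
from . import genomescan, inversions, synthdata, telemetry

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "fjordflow_out"
    seed: int = 0
    # genotype side: either a VCF + popmap, or a synthetic config
    vcf: str | None = None
    popmap: str | None = None
    geno_sim: dict = field(default_factory=dict)
    window_sizes: list[int] = field(default_factory=lambda: [50_000, 100_000])
    filter_params: dict = field(default_factory=dict)
    inversion_regions: dict[str, list[int]] = field(default_factory=dict)  # chrom -> [start, end]
    bootstrap_B: int = 100_000
    # telemetry side
    detections_csv: str | None = None
    telem_sim: dict = field(default_factory=dict)
    timezone: str = telemetry.DEFAULT_TZ

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for w in self.window_sizes:
            if w <= 0:
                raise ValueError("window sizes must be positive")
        for chrom, (start, end) in self.inversion_regions.items():
            if start >= end:
                raise ValueError(f"inversion region {chrom}: start >= end")
        if self.vcf is not None and self.popmap is None:
            raise ValueError("a VCF input needs a popmap")


def _hash_params(**kw) -> str:
    payload = json.dumps(kw, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class _Stage:
    """Content-hash cached stage: skipped when output + matching manifest exist."""

    def __init__(self, out_dir: Path, name: str, params: dict):
        self.name = name
        self.out_dir = out_dir
        self.params = params
        self.key = _hash_params(stage=name, **params)
        self.manifest = out_dir / f"{name}.provenance.json"

    def fresh(self, outputs: list[Path]) -> bool:
        if not self.manifest.exists() or not all(p.exists() for p in outputs):
            return False
        with open(self.manifest) as fh:
            return json.load(fh).get("key") == self.key

    def write_manifest(self, outputs: list[Path]) -> None:
        with open(self.manifest, "w") as fh:
            json.dump(
                {"stage": self.name, "key": self.key, "params": self.params,
                 "outputs": [str(p) for p in outputs]},
                fh, indent=2, default=str,
            )


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute all configured stages in dependency order.

    Returns a mapping of artefact name -> path.  A stage failure raises
    with the failing stage named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    def run_stage(name: str, params: dict, outputs: list[Path], fn) -> None:
        stage = _Stage(out, name, params)
        if stage.fresh(outputs):
            logger.info("stage %s: cached", name)
        else:
            logger.info("stage %s: running", name)
            try:
                fn()
            except Exception as e:  # noqa: BLE001
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            stage.write_manifest(outputs)
        for p in outputs:
            artefacts[p.stem] = p

    # --- genotype chain -----------------------------------------------------
    vcf_path = Path(cfg.vcf) if cfg.vcf else out / "genotypes.vcf"
    popmap_path = Path(cfg.popmap) if cfg.popmap else out / "popmap.tsv"
    truth_path = out / "geno_truth.json"

    if cfg.vcf is None:
        sim_params = dict(cfg.geno_sim)
        sim_params.setdefault("seed", cfg.seed)

        def geno_sim() -> None:
            inv_specs = [
                synthdata.InversionSpec(**s) for s in sim_params.pop("inversion_specs", [])
            ]
            g, truth = synthdata.simulate_genotypes(
                synthdata.GenoSimConfig(**{**sim_params, "inversion_specs": inv_specs})
            )
            gio.write_vcf(g, vcf_path)
            gio.write_popmap(g, popmap_path)
            truth_path.write_text(truth.to_json())

        run_stage("simulate_genotypes", dict(cfg.geno_sim, seed=cfg.seed),
                  [vcf_path, popmap_path, truth_path], geno_sim)

    filt_vcf = out / "filtered.vcf"
    report_path = out / "filter_report.json"

    def filter_stage() -> None:
        g = gio.load_genotypes(vcf_path, popmap_path)
        g = gio.apply_genotype_filters(g, **cfg.filter_params.get("genotype", {}))
        g, report = gio.apply_site_filters(g, **cfg.filter_params.get("site", {}))
        prune = cfg.filter_params.get("ld_prune", {})
        if prune.get("enabled", True):
            g = gio.ld_prune(
                g, window_bp=prune.get("window_bp", 10_000), r2_max=prune.get("r2_max", 0.8)
            )
        gio.write_vcf(g, filt_vcf)
        report_path.write_text(report.to_json())

    run_stage("filter", dict(cfg.filter_params, vcf=str(vcf_path)),
              [filt_vcf, report_path], filter_stage)

    scan_paths = [out / f"scan_{w}.tsv" for w in cfg.window_sizes]

    def scan_stage() -> None:
        g = gio.load_genotypes(filt_vcf, popmap_path)
        pops = list(dict.fromkeys(g.populations))
        for w, p in zip(cfg.window_sizes, scan_paths):
            genomescan.scan(g, pops, w).to_csv(p, sep="\t", index=False)

    run_stage("scan", {"windows": cfg.window_sizes, "vcf": str(filt_vcf)},
              scan_paths, scan_stage)

    if cfg.inversion_regions:
        karyo_path = out / "karyotypes.tsv"
        boot_path = out / "bootstrap.json"

        def inversion_stage() -> None:
            g = gio.load_genotypes(vcf_path, popmap_path)
            popmap = dict(zip(g.samples, g.populations))
            all_calls = []
            for chrom, (start, end) in cfg.inversion_regions.items():
                region = inversions.InversionRegion(chrom, start, end)
                all_calls.extend(inversions.call_region(g, region, seed=cfg.seed))
            pd.DataFrame(
                [
                    {"individual": c.individual, "region": c.region, "state": c.state,
                     "pc1": c.pc1_score, "confidence": c.confidence}
                    for c in all_calls
                ]
            ).to_csv(karyo_path, sep="\t", index=False)
            table = inversions.arrangement_frequencies(all_calls, popmap)
            results = inversions.bootstrap_overrep_test(table, B=cfg.bootstrap_B, seed=cfg.seed)
            boot_path.write_text(
                json.dumps([asdict(r) for r in results], indent=2, default=str)
            )

        run_stage("inversions",
                  {"regions": cfg.inversion_regions, "B": cfg.bootstrap_B, "seed": cfg.seed},
                  [karyo_path, boot_path], inversion_stage)

    # --- telemetry chain ----------------------------------------------------
    if cfg.detections_csv is not None or cfg.telem_sim:
        det_path = Path(cfg.detections_csv) if cfg.detections_csv else out / "detections.csv"
        telem_truth_path = out / "telem_truth.json"
        if cfg.detections_csv is None:
            def telem_sim() -> None:
                tcfg = synthdata.TelemSimConfig(**{**cfg.telem_sim, "seed": cfg.seed})
                det, truth = synthdata.simulate_detections(tcfg)
                synthdata.write_detections_csv(det, det_path)
                telem_truth_path.write_text(truth.to_json())

            run_stage("simulate_detections", dict(cfg.telem_sim, seed=cfg.seed),
                      [det_path, telem_truth_path], telem_sim)

        traits_path = out / "monthly_traits.tsv"
        fates_path = out / "fates.tsv"

        def telem_stage() -> None:
            det = synthdata.read_detections_csv(det_path)
            det = telemetry.filter_false_detections(det, tz=cfg.timezone)
            det_t, _ = telemetry.truncate_post_mortem(det)
            lat = det["lat"].mean()
            lon = det["lon"].mean()
            traits = telemetry.monthly_traits(det_t, lat, lon, tz=cfg.timezone)
            traits.to_csv(traits_path, sep="\t", index=False)
            receivers = det[["receiver_id", "lon", "lat"]].drop_duplicates("receiver_id")
            battery_end = det["timestamp"].max()
            fates = telemetry.classify_fate(det, receivers, battery_end)
            telemetry.relative_longevity(fates)
            pd.DataFrame(
                [
                    {"fish_id": f.fish_id, "fate": f.fate,
                     "days_survived": f.days_survived,
                     "relative_longevity": f.relative_longevity}
                    for f in fates
                ]
            ).to_csv(fates_path, sep="\t", index=False)

        run_stage("telemetry", {"detections": str(det_path), "tz": cfg.timezone},
                  [traits_path, fates_path], telem_stage)

    manifest = out / "run_manifest.json"
    manifest.write_text(
        json.dumps({"seed": cfg.seed, "artefacts": {k: str(v) for k, v in artefacts.items()}},
                   indent=2)
    )
    artefacts["run_manifest"] = manifest
    return artefacts
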