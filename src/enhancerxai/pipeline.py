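"""End-to-end pipeline: simulate -> dataset -> train -> evaluate -> call
-> link -> characterize, driven by one YAML config with a manifest for
provenance and no-op re-runs."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as exio
from .calling import CallingConfig, call_regions, compare_to_reference, regions_to_frame
from .fuzzy import RuleBase
from .induction import InductionConfig, cross_cell_apply, evaluate, induce_rulebase
from .linkage import (
    flag_enriched_contacts,
    link_enhancers_to_promoters,
    linkage_frame,
    linked_expression,
    promoter_intervals,
)
from .profiles import (
    annotation_category_map,
    directionality_frame,
    directionality_score,
    enrichment_frame,
    feature_overlap_enrichment,
    obs_exp_signal_enrichment,
    profile_matrix,
    winsorize_rescale,
)
from .synth import SyntheticConfig, simulate_to_dir
from .tracks import (
    BinDataset,
    build_dataset,
    expand_peaks,
    label_bins,
    map_signal_to_bins,
    minmax_normalize,
    sample_training_set,
    tile_genome,
)

log = logging.getLogger("enhancerxai")

STAGES = ("simulate", "dataset", "train", "evaluate", "call", "link", "characterize")

#: which earlier stage produces the inputs each stage needs
STAGE_REQUIRES = {
    "simulate": None,
    "dataset": "simulate",
    "train": "dataset",
    "evaluate": "train",
    "call": "train",
    "link": "call",
    "characterize": "call",
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "pipeline_out")
    return cfg


class Pipeline:
    def __init__(self, config: dict, force: bool = False):
        self.config = config
        self.force = force
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {}

    # -- manifest helpers ---------------------------------------------------

    def _record(self, stage: str, inputs: list[Path], params: dict, outputs: list[Path]):
        self.manifest[stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "params": params,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _unchanged(self, stage: str, inputs: list[Path], params: dict) -> bool:
        if self.force or stage not in self.manifest:
            return False
        entry = self.manifest[stage]
        if entry["params"] != json.loads(json.dumps(params)):
            return False
        if set(entry["inputs"]) != {str(p) for p in inputs}:
            return False
        for p, digest in entry["inputs"].items():
            if not Path(p).exists() or _sha256(Path(p)) != digest:
                return False
        return all(Path(p).exists() for p in entry["outputs"])

    def _require(self, stage: str, *paths: Path):
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            producer = STAGE_REQUIRES.get(stage)
            raise PipelineError(
                f"stage {stage!r} is missing inputs {[str(p) for p in missing]}; "
                f"run stage {producer!r} first"
            )

    # -- stages -------------------------------------------------------------

    @property
    def simdir(self) -> Path:
        return self.outdir / "synthetic"

    def stage_simulate(self):
        params = dict(self.config.get("synthetic", {}))
        params.setdefault("seed", self.seed)
        cfg = SyntheticConfig.from_mapping(params)
        if self._unchanged("simulate", [], params):
            log.info("simulate: up to date")
            return
        log.info("simulate: generating synthetic genome")
        paths = simulate_to_dir(cfg, self.simdir)
        self._record("simulate", [], params, [Path(p) for p in paths.values()])

    def stage_dataset(self):
        params = dict(self.config.get("dataset", {}))
        width = int(params.get("bin_width", 10))
        # labels.bedGraph already carries bin-resolution labels, so no peak
        # expansion by default; set expand_to (e.g. 400) for raw peak input
        expand_to = int(params.get("expand_to", 0))
        exclude = params.get("exclude", [])
        sizes_path = self.simdir / "chrom.sizes"
        peaks_path = self.simdir / "labels.bedGraph"
        self._require("dataset", sizes_path, peaks_path)
        track_paths = sorted((self.simdir / "tracks").glob("*.bedGraph"))
        inputs = [sizes_path, peaks_path, *track_paths]
        if self._unchanged("dataset", inputs, params):
            log.info("dataset: up to date")
            return
        log.info("dataset: binning genome and mapping tracks")
        sizes = exio.read_chrom_sizes(sizes_path)
        bins = tile_genome(sizes, width, exclude)
        tracks = {}
        order = []
        for path in track_paths:
            mark = path.stem
            records = exio.read_signal(path)
            tracks[mark] = minmax_normalize(map_signal_to_bins(records, bins, mark))
            order.append(mark)
        peaks = exio.read_bedgraph(peaks_path)[["chrom", "start", "end"]]
        if expand_to > 0:
            peaks = expand_peaks(peaks, sizes, expand_to)
        labels = label_bins(bins, peaks)
        dataset = build_dataset(bins, tracks, labels, order)
        ds_dir = self.outdir / "dataset"
        dataset.save(ds_dir)
        self._record(
            "dataset", inputs, params, [ds_dir / "dataset.tsv", ds_dir / "dataset.json"]
        )

    def stage_train(self):
        params = dict(self.config.get("induction", {}))
        params.setdefault("seed", self.seed)
        sample_n = params.pop("sample_n", None)
        test_fraction = params.pop("test_fraction", 0.3)
        ds_dir = self.outdir / "dataset"
        self._require("train", ds_dir / "dataset.tsv")
        inputs = [ds_dir / "dataset.tsv"]
        all_params = {**params, "sample_n": sample_n, "test_fraction": test_fraction}
        if self._unchanged("train", inputs, all_params):
            log.info("train: up to date")
            return
        log.info("train: inducing rule base")
        dataset = BinDataset.load(ds_dir)
        n = sample_n or dataset.n_bins
        n = min(int(n), dataset.n_bins)
        train, test = sample_training_set(
            dataset, n, test_fraction, seed=int(params.get("seed", self.seed))
        )
        cfg = InductionConfig(**params)
        rulebase = induce_rulebase(train, cfg)
        model_path = self.outdir / "model.json"
        rulebase.save(model_path)
        (self.outdir / "rules.txt").write_text(rulebase.to_text())
        split_dir = self.outdir / "splits"
        train.save(split_dir / "train")
        test.save(split_dir / "test")
        self._record(
            "train",
            inputs,
            all_params,
            [
                model_path,
                self.outdir / "rules.txt",
                split_dir / "train" / "dataset.tsv",
                split_dir / "test" / "dataset.tsv",
            ],
        )

    def stage_evaluate(self):
        params = dict(self.config.get("evaluation", {}))
        threshold = float(params.get("threshold", 0.5))
        model_path = self.outdir / "model.json"
        test_dir = self.outdir / "splits" / "test"
        self._require("evaluate", model_path, test_dir / "dataset.tsv")
        inputs = [model_path, test_dir / "dataset.tsv"]
        if self._unchanged("evaluate", inputs, params):
            log.info("evaluate: up to date")
            return
        log.info("evaluate: scoring held-out bins")
        rulebase = RuleBase.load(model_path)
        test = BinDataset.load(test_dir)
        cm, report = evaluate(rulebase, test, threshold)
        report_path = self.outdir / "report.tsv"
        pd.DataFrame(
            {"metric": list(report.as_dict()), "value": list(report.as_dict().values())}
        ).to_csv(report_path, sep="\t", index=False, float_format="%.6g")
        confusion_path = self.outdir / "confusion.tsv"
        pd.DataFrame(
            {"count": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}}
        ).to_csv(confusion_path, sep="\t", index_label="cell")
        self._record("evaluate", inputs, params, [report_path, confusion_path])

    def stage_call(self):
        params = dict(self.config.get("calling", {}))
        model_path = self.outdir / "model.json"
        ds_dir = self.outdir / "dataset"
        ref_path = self.simdir / "true_enhancers.bed"
        self._require("call", model_path, ds_dir / "dataset.tsv")
        inputs = [model_path, ds_dir / "dataset.tsv"]
        if ref_path.exists():
            inputs.append(ref_path)
        if self._unchanged("call", inputs, params):
            log.info("call: up to date")
            return
        log.info("call: thresholding and merging regions")
        rulebase = RuleBase.load(model_path)
        dataset = BinDataset.load(ds_dir)
        sizes = {
            c: int(dataset.ends[dataset.chrom_codes == i].max())
            for i, c in enumerate(dataset.chrom_order)
        }
        bins = tile_genome(sizes, dataset.bin_width)
        probs = cross_cell_apply(rulebase, dataset)
        cfg = CallingConfig(
            threshold=float(params.get("threshold", 0.8)),
            merge_gap=int(params.get("merge_gap", 100)),
        )
        regions = call_regions(probs, bins, cfg)
        summary: dict[str, int] = {}
        if ref_path.exists():
            reference = exio.read_bed(ref_path)[["chrom", "start", "end"]]
            regions, _, summary = compare_to_reference(regions, reference)
        calls_path = self.outdir / "calls.bed"
        exio.write_bed(regions_to_frame(regions), calls_path)
        summary_path = self.outdir / "call_summary.tsv"
        with open(summary_path, "w") as fh:
            fh.write("class\tcount\n")
            for key, value in sorted(summary.items()):
                fh.write(f"{key}\t{value}\n")
            sizes_count: dict[str, int] = {}
            for region in regions:
                sizes_count[region.size_class] = sizes_count.get(region.size_class, 0) + 1
            for key, value in sorted(sizes_count.items()):
                fh.write(f"size:{key}\t{value}\n")
        self._record("call", inputs, params, [calls_path, summary_path])

    def stage_link(self):
        params = dict(self.config.get("linkage", {}))
        proximal = int(params.get("proximal_distance", 5000))
        ratio = float(params.get("ratio_threshold", 2.0))
        fpkm_thr = float(params.get("fpkm_threshold", 1.0))
        calls_path = self.outdir / "calls.bed"
        gff_path = self.simdir / "annotation.gff3"
        contacts_path = self.simdir / "contacts.tsv"
        fpkm_path = self.simdir / "fpkm.tsv"
        self._require("link", calls_path, gff_path, contacts_path, fpkm_path)
        inputs = [calls_path, gff_path, contacts_path, fpkm_path]
        if self._unchanged("link", inputs, params):
            log.info("link: up to date")
            return
        log.info("link: promoter contacts and expression")
        from .calling import regions_from_frame

        regions = regions_from_frame(exio.read_bed(calls_path))
        genes = exio.read_gff3(gff_path)
        contacts = flag_enriched_contacts(exio.read_contacts(contacts_path), ratio)
        promoters = promoter_intervals(genes)
        linkages = link_enhancers_to_promoters(regions, promoters, contacts, proximal)
        fpkm = exio.read_fpkm(fpkm_path)
        linked_expression(linkages, fpkm, fpkm_thr)
        out_path = self.outdir / "linkage.tsv"
        linkage_frame(linkages).to_csv(
            out_path, sep="\t", index=False, float_format="%.6g"
        )
        self._record("link", inputs, params, [out_path])

    def stage_characterize(self):
        params = dict(self.config.get("profiles", {}))
        flank = int(params.get("flank", 5000))
        calls_path = self.outdir / "calls.bed"
        ds_dir = self.outdir / "dataset"
        plus_path = self.simdir / "nascent_plus.bedGraph"
        minus_path = self.simdir / "nascent_minus.bedGraph"
        gff_path = self.simdir / "annotation.gff3"
        self._require(
            "characterize", calls_path, ds_dir / "dataset.tsv", plus_path, minus_path
        )
        inputs = [calls_path, ds_dir / "dataset.tsv", plus_path, minus_path, gff_path]
        if self._unchanged("characterize", inputs, params):
            log.info("characterize: up to date")
            return
        log.info("characterize: profiles, directionality, enrichment")
        from .calling import regions_from_frame

        regions = regions_from_frame(exio.read_bed(calls_path))
        dataset = BinDataset.load(ds_dir)
        sizes = {
            c: int(dataset.ends[dataset.chrom_codes == i].max())
            for i, c in enumerate(dataset.chrom_order)
        }
        bins = tile_genome(sizes, dataset.bin_width)
        outdir = self.outdir / "characterize"
        outdir.mkdir(exist_ok=True)
        outputs = []

        plus = map_signal_to_bins(exio.read_bedgraph(plus_path), bins, "plus").values
        minus = map_signal_to_bins(exio.read_bedgraph(minus_path), bins, "minus").values
        records = []
        for region in regions:
            rec = directionality_score(plus, minus, region, bins)
            if rec is not None:
                records.append(rec)
        dir_path = outdir / "directionality.tsv"
        directionality_frame(records).to_csv(
            dir_path, sep="\t", index=False, float_format="%.6g"
        )
        outputs.append(dir_path)

        enr_records = []
        groups: dict[str, list] = {}
        for region in regions:
            groups.setdefault(region.origin or "all", []).append(region)
        for j, mark in enumerate(dataset.feature_order):
            for group, group_regions in sorted(groups.items()):
                enr_records.append(
                    obs_exp_signal_enrichment(
                        dataset.X[:, j], group_regions, bins, f"{group}:{mark}"
                    )
                )
        if gff_path.exists():
            genes = exio.read_gff3(gff_path)
            category_map = annotation_category_map(genes, bins)
            for group, group_regions in sorted(groups.items()):
                enr_records.extend(
                    feature_overlap_enrichment(group_regions, category_map, group)
                )
        enr_path = outdir / "enrichment.tsv"
        enrichment_frame(enr_records).to_csv(
            enr_path, sep="\t", index=False, float_format="%.6g"
        )
        outputs.append(enr_path)

        if regions and dataset.feature_order:
            matrix = winsorize_rescale(
                profile_matrix(dataset.X[:, 0], regions, bins, flank)
            )
            mat_path = outdir / f"profile_{dataset.feature_order[0]}.tsv"
            pd.DataFrame(
                matrix.values, index=matrix.region_ids, columns=matrix.offsets
            ).to_csv(mat_path, sep="\t", float_format="%.6g", index_label="region")
            outputs.append(mat_path)
        self._record("characterize", inputs, params, outputs)

    # -- driver -------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        todo = list(stages) if stages else list(STAGES)
        unknown = [s for s in todo if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        todo.sort(key=STAGES.index)
        for stage in todo:
            getattr(self, f"stage_{stage}")()
        return self.manifest


def run_pipeline(
    config: dict, stages: list[str] | None = None, force: bool = False
) -> dict:
    """Run the requested stages (all by default) in dependency order;
    returns the manifest.  Outputs are a pure function of (config, seed)."""
    return Pipeline(config, force=force).run(stages)
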