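"""End-to-end orchestration: synthesize-or-load -> features -> matrices ->
PCA/OPLS-DA models -> motif -> peaks -> 3'-bias -> null models -> report.

A single global seed is fanned out into named sub-streams (synthesis, the
train/test split, cross-validation folds, null-model sampling) so stages
can be re-run independently and the whole report bundle is reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import chip, features as feat, gene_classes, kmer, motif as motif_mod
from . import multivariate as mv
from . import synth as synth_mod
from .errors import ConfigError, InputError
from .motif import AlignerParams
from .synth import SynthConfig

log = logging.getLogger("mslseq")

STAGES = ("data", "features", "matrix", "pca", "classify", "oplsda",
          "motif", "peaks", "thirds", "null", "report")


@dataclass
class PipelineConfig:
    """All fixed constants of the analysis, with their standard defaults."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    data_dir: str | None = None  # load a written dataset instead of synthesizing
    k_min: int = 2
    k_max: int = 6
    promoter_bp: int = 500
    train_fraction: float = 2.0 / 3.0
    strong_threshold: float = 1.0
    weak_threshold: float = 0.5
    expression_window: tuple[float, float] = (6.0, 10.0)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    peak_sd_mult: float = 3.0
    peak_min_span: int = 360
    peak_max_gap: int = 360
    peak_min_probes: int = 5
    null_groups: int = 7
    null_group_size: int | None = None
    enrichment_bin_width: float = 0.2
    coloc_bin: int = 100
    coloc_span: int = 2000
    max_orth: int = 5
    cv_folds: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.data_dir is not None and not os.path.isdir(self.data_dir):
            raise ConfigError(f"data_dir {self.data_dir!r} does not exist")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def binned_enrichment_summary(
    class_table: pd.DataFrame,
    presence_flags: pd.Series,
    bin_width: float = 0.2,
) -> pd.Series:
    """Fraction of genes carrying a presence flag per average-MSL-enrichment
    bin; bins with no genes are NaN (missing, not zero)."""
    genes = class_table.index.intersection(presence_flags.index)
    avg = class_table.loc[genes, "avg_msl"]
    flags = presence_flags.loc[genes].astype(bool)
    lo = np.floor(avg.min() / bin_width) * bin_width
    hi = np.ceil(avg.max() / bin_width) * bin_width + 1e-9
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.digitize(avg, edges) - 1
    out = {}
    for b in range(len(edges) - 1):
        sel = idx == b
        out[round(float(edges[b]), 10)] = (
            float(flags[sel].mean()) if sel.any() else float("nan")
        )
    return pd.Series(out, name="presence_fraction")


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def gene_feature_sequences(features_list) -> dict[str, dict[str, str]]:
    """Per-gene transcript-ordered sequence of each feature class."""
    groups: dict[str, dict[str, list]] = {}
    strands: dict[str, str] = {}
    for fc in features_list:
        if fc.owner_gene == "intergenic" or fc.excluded:
            continue
        groups.setdefault(fc.feature_class, {}).setdefault(fc.owner_gene, []).append(fc)
        strands[fc.owner_gene] = fc.strand
    out: dict[str, dict[str, str]] = {}
    for cls, per_gene in groups.items():
        out[cls] = {}
        for gid, pieces in per_gene.items():
            pieces.sort(key=lambda f: f.start, reverse=strands[gid] == "-")
            out[cls][gid] = "".join(p.bases for p in pieces)
    return out


class Pipeline:
    """Stateful runner; stages cache their products on the instance."""

    def __init__(self, config: PipelineConfig, outdir: str | None = None):
        config.validate()
        self.config = config
        self.outdir = outdir
        if outdir:
            os.makedirs(outdir, exist_ok=True)
        ss = np.random.SeedSequence(config.seed)
        kids = ss.spawn(4)
        self.seed_synth = _child_seed(kids[0])
        self.seed_split = _child_seed(kids[1])
        self.seed_cv = _child_seed(kids[2])
        self.seed_null = _child_seed(kids[3])
        self.report: dict = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }

    def _path(self, name: str) -> str | None:
        return os.path.join(self.outdir, name) if self.outdir else None

    def _timed(self, stage: str):
        log.info("stage %s ...", stage)
        return time.perf_counter()

    # ------------------------------------------------------------------
    def stage_data(self):
        t0 = self._timed("data")
        cfg = self.config
        if cfg.data_dir:
            d = cfg.data_dir
            genome = feat.read_fasta(os.path.join(d, "genome.fa"))
            with open(os.path.join(d, "annotation.gff3")) as fh:
                gff3 = fh.read()
            trackdir = os.path.join(d, "tracks")
            tracks = {
                fn[: -len(".bedGraph")]: chip.read_bedgraph(os.path.join(trackdir, fn))
                for fn in sorted(os.listdir(trackdir))
                if fn.endswith(".bedGraph")
            }
            expression = pd.read_csv(
                os.path.join(d, "expression.tsv"), sep="\t", index_col=0
            )
            truth_path = os.path.join(d, "truth.json")
            truth = (
                synth_mod.SynthTruth.from_json(truth_path)
                if os.path.exists(truth_path)
                else None
            )
            self.dataset = synth_mod.SynthDataset(
                genome=genome, gff3=gff3, probe_tracks=tracks,
                expression=expression, truth=truth,
            )
        else:
            scfg = dataclasses.replace(cfg.synth, seed=self.seed_synth)
            self.dataset = synth_mod.generate_dataset(scfg)
            if self.outdir:
                synth_mod.write_dataset(self.dataset, os.path.join(self.outdir, "data"))
        log.info("stage data done in %.1fs", time.perf_counter() - t0)
        return self.dataset

    def stage_features(self):
        t0 = self._timed("features")
        ds = self.dataset
        self.genes = feat.parse_annotation(ds.gff3)
        self.chrom_lengths = {c: len(s) for c, s in ds.genome.items()}
        coords = feat.derive_features(
            self.genes, self.chrom_lengths, promoter_bp=self.config.promoter_bp
        )
        self.features = feat.extract_sequences(coords, ds.genome)
        self.by_gene = gene_feature_sequences(self.features)
        if self.outdir:
            feat.write_bed6(self.features, self._path("features.bed"))
        self.report["n_genes"] = len(self.genes)
        log.info("stage features done in %.1fs", time.perf_counter() - t0)

    def stage_matrix(self):
        t0 = self._timed("matrix")
        cfg = self.config
        pooled: dict[str, list[str]] = {}
        for fc in self.features:
            key = f"{fc.feature_class}|{fc.chrom}"
            pooled.setdefault(key, []).append(fc.bases)
        self.feature_matrix = kmer.build_word_matrix(
            pooled, cfg.k_min, cfg.k_max, layout="as_published"
        )
        if self.outdir:
            self.feature_matrix.to_tsv(self._path("feature_matrix.tsv"))
        self.report["feature_matrix_rows"] = int(self.feature_matrix.data.shape[0])
        self.report["feature_matrix_cols"] = int(self.feature_matrix.data.shape[1])
        log.info("stage matrix done in %.1fs", time.perf_counter() - t0)

    def stage_pca(self):
        t0 = self._timed("pca")
        normed = kmer.at_normalize(self.feature_matrix)
        scaled = kmer.scale_matrix(normed, "centered")
        n_comp = min(6, scaled.data.shape[0] - 1)
        self.feature_pca = mv.fit_pca(scaled, n_comp)
        # raw-frequency PCA for the AT-content comparison
        raw_scaled = kmer.scale_matrix(self.feature_matrix, "uv_scaled")
        self.feature_pca_raw = mv.fit_pca(raw_scaled, n_comp)
        from scipy.stats import spearmanr

        at = self.feature_matrix.at_content.to_numpy()
        rho_raw = spearmanr(self.feature_pca_raw.scores["PC1"], at).statistic
        rho_norm = spearmanr(self.feature_pca.scores["PC1"], at).statistic
        self.report["feature_pca_r2cum"] = [round(float(v), 6) for v in self.feature_pca.r2cum]
        self.report["pc1_at_spearman_raw"] = float(rho_raw)
        self.report["pc1_at_spearman_normalized"] = float(rho_norm)
        if self.outdir:
            self.feature_pca.scores.to_csv(self._path("feature_pca_scores.tsv"), sep="\t")
            self.feature_pca.loadings.to_csv(self._path("feature_pca_loadings.tsv"), sep="\t")
        log.info("stage pca done in %.1fs", time.perf_counter() - t0)

    def stage_classify(self):
        t0 = self._timed("classify")
        cfg = self.config
        msl = [p for p in self.dataset.probe_tracks if not p.startswith("BEAF")]
        binding = chip.gene_binding_table(
            {p: self.dataset.probe_tracks[p] for p in msl}, self.genes
        )
        self.class_table = gene_classes.classify_genes(
            binding,
            self.dataset.expression,
            strong_threshold=cfg.strong_threshold,
            weak_threshold=cfg.weak_threshold,
            expression_window=cfg.expression_window,
        )
        counts = self.class_table["gene_class"].value_counts().to_dict()
        self.report["class_counts"] = {k: int(v) for k, v in sorted(counts.items())}
        if self.outdir:
            self.class_table.to_csv(self._path("class_table.tsv"), sep="\t")
        # class-level PCA (pooled observations per class x feature)
        per_class: dict[str, list[str]] = {}
        keep = ("strong_expressed", "weak_expressed", "unexpressed")
        for cls_name in self.by_gene:
            for gid, seq in self.by_gene[cls_name].items():
                if gid not in self.class_table.index:
                    continue
                gcls = self.class_table.loc[gid, "gene_class"]
                if gcls not in keep:
                    continue
                per_class.setdefault(f"{gcls}|{cls_name}", []).append(seq)
        cm = kmer.build_word_matrix(per_class, cfg.k_min, cfg.k_max, "as_published")
        scaled = kmer.scale_matrix(kmer.at_normalize(cm), "centered")
        self.class_pca = mv.fit_pca(scaled, min(4, scaled.data.shape[0] - 1))
        self.report["class_pca_r2cum"] = [round(float(v), 6) for v in self.class_pca.r2cum]
        log.info("stage classify done in %.1fs", time.perf_counter() - t0)

    # ------------------------------------------------------------------
    def _model_sets(self, feature_class: str):
        """Strong/weak expressed genes possessing the feature, train/test."""
        seqs = self.by_gene.get(feature_class, {})
        table = self.class_table
        genes = [
            g for g in seqs
            if g in table.index
            and table.loc[g, "gene_class"] in ("strong_expressed", "weak_expressed")
        ]
        labels = ["strong" if table.loc[g, "gene_class"] == "strong_expressed"
                  else "weak" for g in genes]
        train, test = train_test_split(
            np.arange(len(genes)),
            train_size=self.config.train_fraction,
            stratify=labels,
            random_state=self.seed_split,
        )
        tr_genes = [genes[i] for i in sorted(train)]
        te_genes = [genes[i] for i in sorted(test)]
        return seqs, tr_genes, te_genes, dict(zip(genes, labels))

    def _fit_feature_model(self, feature_class: str):
        cfg = self.config
        seqs, tr, te, labels = self._model_sets(feature_class)
        matrix = kmer.build_word_matrix(
            {g: seqs[g] for g in tr}, cfg.k_min, cfg.k_max, "canonical"
        )
        model = mv.fit_oplsda(
            matrix,
            [labels[g] for g in tr],
            n_orth="auto",
            positive_class="strong",
            max_orth=cfg.max_orth,
            cv_folds=cfg.cv_folds,
            seed=self.seed_cv,
        )
        test_matrix = kmer.build_word_matrix(
            {g: seqs[g] for g in te}, cfg.k_min, cfg.k_max, "canonical"
        )
        scores = mv.predict_scores(model, test_matrix)
        s = scores[[labels[g] == "strong" for g in te]]
        w = scores[[labels[g] == "weak" for g in te]]
        stat, p = gene_classes.compare_groups(s, w, "mann_whitney", "greater")
        return dict(model=model, train=tr, test=te, labels=labels,
                    test_scores=scores, mw_u=stat, mw_p=p)

    def stage_oplsda(self):
        t0 = self._timed("oplsda")
        self.models = {}
        for feature_class in ("promoter", "cds"):
            res = self._fit_feature_model(feature_class)
            self.models[feature_class] = res
            self.report[f"{feature_class}_model_q2"] = float(res["model"].q2)
            self.report[f"{feature_class}_model_n_orth"] = int(res["model"].n_orth)
            self.report[f"{feature_class}_test_mw_p"] = float(res["mw_p"])
            self.report[f"{feature_class}_n_train"] = len(res["train"])
            self.report[f"{feature_class}_n_test"] = len(res["test"])
            if self.outdir:
                res["model"].to_json(self._path(f"{feature_class}_model.json"))
                res["model"].loadings_to_tsv(self._path(f"{feature_class}_loadings.tsv"))
        log.info("stage oplsda done in %.1fs", time.perf_counter() - t0)

    def stage_motif(self):
        t0 = self._timed("motif")
        cfg = self.config
        res = self.models["promoter"]
        seqs = self.by_gene["promoter"]
        loadings = res["model"].sorted_loadings()
        words = list(loadings.items())[: cfg.aligner.top_n_words]
        pos = [seqs[g] for g in res["train"] if res["labels"][g] == "strong"]
        neg = [seqs[g] for g in res["train"] if res["labels"][g] == "weak"]
        self.motifs = motif_mod.build_motifs(words, pos, neg, cfg.aligner)
        self.report["n_motifs"] = len(self.motifs)
        if not self.motifs:
            log.info("stage motif: no accepted motif")
            return
        m = self.motifs[0]
        te_s = [seqs[g] for g in res["test"] if res["labels"][g] == "strong"]
        te_w = [seqs[g] for g in res["test"] if res["labels"][g] == "weak"]
        self.report["motif_consensus"] = m.consensus()
        self.report["motif_length"] = int(m.length)
        self.report["motif_cutoff"] = float(m.cutoff)
        self.report["motif_fraction_strong_test"] = motif_mod.motif_presence_fraction(
            m, te_s, window=cfg.promoter_bp
        )
        self.report["motif_fraction_weak_test"] = motif_mod.motif_presence_fraction(
            m, te_w, window=cfg.promoter_bp
        )
        # Fraction with the motif per average-MSL-enrichment bin, over all
        # expressed genes with a modellable promoter.
        expressed = self.class_table[
            self.class_table["gene_class"].isin(
                ("strong_expressed", "weak_expressed", "intermediate")
            )
        ]
        flags = {}
        for gid in expressed.index:
            if gid in seqs and len(seqs[gid]) >= m.length:
                flags[gid] = (
                    motif_mod.score_pwm(m, seqs[gid][-cfg.promoter_bp:], top_n=1)
                    >= m.cutoff
                )
        flags = pd.Series(flags)
        binned = binned_enrichment_summary(
            expressed, flags, cfg.enrichment_bin_width
        )
        self.motif_enrichment_bins = binned
        self.report["motif_fraction_by_msl_bin"] = {
            str(k): (None if np.isnan(v) else round(float(v), 6))
            for k, v in binned.items()
        }
        if self.outdir:
            motif_mod.write_meme(self.motifs, self._path("motifs.meme"))
            motif_mod.write_pwm_tsv(m, self._path("motif1_pwm.tsv"))
        log.info("stage motif done in %.1fs", time.perf_counter() - t0)

    def stage_peaks(self):
        t0 = self._timed("peaks")
        cfg = self.config
        ds = self.dataset
        abs_ = sorted(p for p in ds.probe_tracks if p.startswith("BEAF"))
        called = {}
        for ab in abs_:
            called[ab] = chip.call_regions(
                ds.probe_tracks[ab],
                sd_mult=cfg.peak_sd_mult,
                min_span=cfg.peak_min_span,
                max_gap=cfg.peak_max_gap,
                min_probes=cfg.peak_min_probes,
            )
            self.report[f"n_regions_{ab}"] = len(called[ab])
        if len(abs_) >= 2:
            peaks = chip.intersect_regions(called[abs_[0]], called[abs_[1]])
        else:
            peaks = called[abs_[0]]
        self.peaks = peaks
        self.report["n_peaks_intersected"] = len(peaks)
        if self.outdir:
            chip.write_peaks_bed(peaks, self._path("peaks.bed"))

        dist = chip.tss_peak_distance(self.genes, peaks)
        table = self.class_table
        strong = dist[[g.gene_id for g in self.genes
                       if g.gene_id in table.index
                       and table.loc[g.gene_id, "gene_class"] == "strong_expressed"]]
        weak = dist[[g.gene_id for g in self.genes
                     if g.gene_id in table.index
                     and table.loc[g.gene_id, "gene_class"] == "weak_expressed"]]
        stat, p = gene_classes.compare_groups(
            strong.dropna(), weak.dropna(), "mann_whitney", "less"
        )
        self.report["tss_distance_mw_p"] = float(p)
        self.report["beaf_fraction_strong"] = float(
            (strong <= cfg.promoter_bp).mean()
        )
        self.report["beaf_fraction_weak"] = float((weak <= cfg.promoter_bp).mean())
        cov = chip.coverage_fraction(peaks, self.chrom_lengths)
        self.report["peak_coverage_fraction"] = {
            c: round(float(v), 6) for c, v in cov.items()
        }
        # fraction of expressed genes with a peak within 500 bp of the TSS,
        # per average-MSL-enrichment bin
        expressed = table[
            table["gene_class"].isin(
                ("strong_expressed", "weak_expressed", "intermediate")
            )
        ]
        flags = (dist.loc[expressed.index] <= cfg.promoter_bp).fillna(False)
        beaf_bins = binned_enrichment_summary(
            expressed, flags, cfg.enrichment_bin_width
        )
        self.beaf_enrichment_bins = beaf_bins
        self.report["beaf_fraction_by_msl_bin"] = {
            str(k): (None if np.isnan(v) else round(float(v), 6))
            for k, v in beaf_bins.items()
        }
        # MOF co-localization around promoter-proximal peaks
        tss = {g.gene_id: (g.chrom, g.tss) for g in self.genes}
        anchors = []
        for r in peaks:
            best = None
            for gid, (chrom, t) in tss.items():
                if chrom != r.chrom:
                    continue
                d = abs(t - r.center)
                if best is None or d < best[0]:
                    best = (d, t)
            if best is not None and best[0] <= cfg.promoter_bp:
                anchors.append((r.chrom, r.center, best[1] >= r.center))
        if anchors and "MOF" in ds.probe_tracks:
            profile = chip.binned_colocalization(
                ds.probe_tracks["MOF"], anchors, cfg.coloc_bin, cfg.coloc_span
            )
            self.coloc_profile = profile
            peak_bin = profile.idxmax()
            self.report["coloc_n_anchors"] = len(anchors)
            self.report["coloc_peak_bin"] = int(peak_bin)
            if self.outdir:
                profile.to_csv(self._path("coloc_profile.tsv"), sep="\t")
        log.info("stage peaks done in %.1fs", time.perf_counter() - t0)

    def stage_thirds(self):
        t0 = self._timed("thirds")
        res = self.models["cds"]
        seqs = self.by_gene["cds"]
        strong_test = {
            g: seqs[g] for g in res["test"] if res["labels"][g] == "strong"
        }
        scores, result = gene_classes.thirds_bias_test(
            res["model"], strong_test, self.config.k_min, self.config.k_max
        )
        self.thirds_scores = scores
        self.report["thirds_bias_t"] = result["statistic"]
        self.report["thirds_bias_p"] = result["p_value"]
        self.report["thirds_n_genes"] = result["n"]
        self.report["thirds_mean_5p"] = float(scores["five_prime"].mean())
        self.report["thirds_mean_mid"] = float(scores["middle"].mean())
        self.report["thirds_mean_3p"] = float(scores["three_prime"].mean())
        if self.outdir:
            scores.to_csv(self._path("thirds_scores.tsv"), sep="\t")
        log.info("stage thirds done in %.1fs", time.perf_counter() - t0)

    def stage_null(self):
        t0 = self._timed("null")
        cfg = self.config
        cds = list(self.by_gene["cds"].values())
        group_size = cfg.null_group_size or max(3, len(cds) // cfg.null_groups)
        null = mv.random_group_null(
            cds,
            n_groups=cfg.null_groups,
            group_size=group_size,
            seed=self.seed_null,
            k_min=cfg.k_min,
            k_max=cfg.k_max,
            folds=min(cfg.cv_folds, group_size),
        )
        self.null_models = null
        self.report["null_n_models"] = int(len(null))
        self.report["null_q2_values"] = [round(float(v), 6) for v in null["q2"]]
        self.report["null_q2_median"] = float(null["q2"].median())
        self.report["null_fraction_negative"] = float((null["q2"] < 0).mean())
        if self.outdir:
            null.to_csv(self._path("null_models.tsv"), sep="\t", index=False)
        log.info("stage null done in %.1fs", time.perf_counter() - t0)

    def stage_report(self):
        if self.outdir:
            with open(self._path("report.json"), "w") as fh:
                json.dump(self.report, fh, indent=1, sort_keys=True)
        return self.report

    # ------------------------------------------------------------------
    def run(self, until: str = "report") -> dict:
        if until not in STAGES:
            raise InputError(f"unknown stage {until!r}")
        stop = STAGES.index(until)
        for stage in STAGES[: stop + 1]:
            getattr(self, f"stage_{stage}")()
        return self.report


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Run the full analysis; returns the report dict (also written as
    report.json when ``outdir`` is given)."""
    return Pipeline(config, outdir).run("report")
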