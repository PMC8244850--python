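"""End-to-end orchestration: delimit -> stats -> hybridize -> fold ->
classify -> align -> distances -> trees -> consensus -> barcode gap.

One call (:func:`run_pipeline`) runs the whole analysis on either a real
FASTA + manifest or a synthetic study configuration, writing a report
bundle of plain-text artifacts (TSV tables, aligned FASTA, dot-bracket
structures, Newick trees, a parameter manifest and a run log).  All
randomness (generator, bootstraps) flows from one master seed via named
substreams, so a fixed configuration reproduces the bundle byte-for-byte.
A stage failure produces a machine-readable error summary and skips the
stages downstream of it.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .its_delimit import (
    DelimitParams,
    DelimitError,
    ItsPartition,
    delimit_its,
    find_flank_motifs,
    flag_pseudogene_candidate,
    hybridize_stem,
)
from .seq_stats import (
    count_indel_events,
    dunn_posthoc,
    group_summary,
    kruskal_wallis,
    normalized_length,
)
from .seqstruct_phylo import (
    AlignParams,
    Alignment,
    RateModel,
    SeqStructAlignParams,
    encode_seqstruct,
    estimate_gamma_shape,
    group_mean_distances,
    msa,
    nj_bootstrap,
    optimize_branch_lengths,
    seqstruct_align,
)
from .sequence_io import (
    GroupManifest,
    SeqRecord,
    read_fasta,
    read_manifest,
    write_fasta,
    write_table,
)
from .structure2d import (
    classify_model,
    consensus_structure,
    decompose_helices,
    detect_motifs,
    fold_mfe,
)
from .synthetic_data import StudyConfig, default_study_config, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("its2kit")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be active."""

    input_fasta: str | None = None
    input_manifest: str | None = None
    synthetic: StudyConfig | None = None
    delimit: DelimitParams = field(default_factory=DelimitParams)
    align: AlignParams = field(default_factory=AlignParams)
    ss_align: SeqStructAlignParams = field(default_factory=SeqStructAlignParams)
    rate: RateModel = field(default_factory=lambda: RateModel(model="K2P", alpha=5.0))
    stem_window: int = 25
    bootstrap_reps: int = 1000
    max_phylo_taxa: int = 25
    out_dir: str = "its2kit_out"
    master_seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        real = self.input_fasta is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of (input_fasta, synthetic) must be provided"
            )
        if real and self.input_manifest is None:
            raise ValueError("a group manifest is required with input_fasta")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        syn = raw["synthetic"] or {}
        kwargs["synthetic"] = default_study_config(
            n_ampelomyces=int(syn.get("n_ampelomyces", 376)),
            master_seed=int(syn.get("seed", raw.get("master_seed", 0))),
        )
    if "input" in raw:
        kwargs["input_fasta"] = raw["input"].get("fasta")
        kwargs["input_manifest"] = raw["input"].get("manifest")
    if "delimit" in raw:
        kwargs["delimit"] = DelimitParams(**raw["delimit"])
    if "rate" in raw:
        kwargs["rate"] = RateModel(**raw["rate"])
    for key in ("bootstrap_reps", "max_phylo_taxa", "out_dir", "master_seed",
                "verbosity", "stem_window"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    counts: dict[str, int]
    artifacts: dict[str, str]
    errors: list[dict]
    barcode_gap: bool | None = None
    log_likelihoods: dict[str, float] = field(default_factory=dict)


def _seed(master: int, stream: int) -> int:
    return int(np.random.default_rng([master, stream]).integers(0, 2**31 - 1))


def _stratified_subset(
    records: list[SeqRecord],
    models: dict[str, str],
    manifest: GroupManifest,
    max_taxa: int,
) -> list[str]:
    """Up to *max_taxa* ids: all non-Ampelomyces + a model-stratified
    sample of Ampelomyces (mirrors the small published tree datasets)."""
    others = [r.id for r in records if r.group != "AMPELOMYCES"]
    amp = [r.id for r in records if r.group == "AMPELOMYCES"]
    budget = max(max_taxa - len(others), 0)
    by_model: dict[str, list[str]] = {}
    for rid in amp:
        by_model.setdefault(models.get(rid, "UNCLASSIFIED"), []).append(rid)
    chosen: list[str] = []
    order = sorted(by_model)
    k = 0
    while len(chosen) < budget and any(by_model.values()):
        m = order[k % len(order)]
        if by_model[m]:
            chosen.append(by_model[m].pop(0))
        k += 1
    return chosen + others


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if cfg.verbosity else logging.WARNING)
    run_log: list[str] = []
    errors: list[dict] = []
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def note(msg: str) -> None:
        log.info(msg)
        run_log.append(msg)

    def fail(stage: str, exc: Exception) -> None:
        errors.append({"stage": stage, "error": f"{type(exc).__name__}: {exc}"})
        note(f"STAGE FAILED: {stage}: {exc}")

    def save_rows(name: str, rows, header, decimals=None) -> None:
        path = out / name
        write_table(rows, path, header=header, decimals=decimals)
        artifacts[name] = str(path)

    # ---- inputs -----------------------------------------------------------
    truth = None
    if cfg.synthetic is not None:
        study = generate_study(cfg.synthetic)
        records, manifest, truth = study.records, study.manifest, study.truth
        write_fasta(records, out / "sequences.fasta")
        artifacts["sequences.fasta"] = str(out / "sequences.fasta")
    else:
        records = read_fasta(cfg.input_fasta)
        manifest = read_manifest(cfg.input_manifest)
        missing = manifest.missing_from(records)
        if missing:
            note(f"manifest ids absent from FASTA: {missing}")
    manifest.label_records(records)
    records = [r for r in records if r.group is not None]
    counts["records"] = len(records)
    note(f"loaded {len(records)} records in "
         f"{len(set(manifest.groups.values()))} groups")

    result = PipelineResult(out_dir=out, counts=counts, artifacts=artifacts,
                            errors=errors)

    # ---- delimitation -----------------------------------------------------
    partitions: dict[str, ItsPartition] = {}
    try:
        rows = []
        for rec in records:
            try:
                hits = find_flank_motifs(rec, cfg.delimit)
                part = delimit_its(rec, hits, cfg.delimit)
            except DelimitError as exc:
                rows.append([rec.id, rec.group, -1, -1, -1, -1, -1, -1, str(exc)])
                continue
            partitions[rec.id] = part
            (a1, a2), (b1, b2), (c1, c2) = part.its1, part.s5_8, part.its2
            # 1-based inclusive coordinates in reports.
            rows.append([rec.id, rec.group, a1 + 1, a2, b1 + 1, b2, c1 + 1, c2, ""])
        save_rows(
            "delimitation.tsv", rows,
            ("id", "group", "its1_start", "its1_end", "s5_8_start", "s5_8_end",
             "its2_start", "its2_end", "error"),
        )
        counts["delimited"] = len(partitions)
        note(f"delimited {len(partitions)}/{len(records)} records")
    except Exception as exc:  # pragma: no cover - defensive
        fail("delimitation", exc)
        return result

    by_id = {r.id: r for r in records}
    group_names = list(dict.fromkeys(manifest.groups.values()))

    # ---- sequence statistics ---------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = group_summary(records, partitions, manifest)
        save_rows(
            "stats_summary.tsv", summary.values.tolist(), list(summary.columns),
            decimals={"len_mean": 2, "len_sem": 3, "norm_mean": 2, "norm_sem": 3,
                      "at_min": 2, "at_max": 2, "gc_min": 2, "gc_max": 2},
        )
        norm_by_group = {
            g: [
                normalized_length(
                    partitions[rid].its_span[1] - partitions[rid].its_span[0]
                )
                for rid in manifest.members(g) if rid in partitions
            ]
            for g in group_names
        }
        groups_in = [g for g in group_names if norm_by_group[g]]
        kw = kruskal_wallis([norm_by_group[g] for g in groups_in])
        dunn = dunn_posthoc(kw)
        test_rows = [["kruskal_wallis", "all", kw.H, kw.df, kw.p]]
        for _, row in dunn.iterrows():
            test_rows.append([
                "dunn", f"{groups_in[int(row.group_i)]}|{groups_in[int(row.group_j)]}",
                row.z, "", row.p,
            ])
        save_rows("stats_tests.tsv", test_rows,
                  ("test", "groups", "statistic", "df", "p"),
                  decimals=[None, None, 4, None, 6])
        note(f"Kruskal-Wallis H={kw.H:.2f} (df={kw.df}, p={kw.p:.3g}) "
             "on normalized ITS lengths")
    except Exception as exc:
        fail("stats", exc)

    # ---- indel analysis ---------------------------------------------------
    try:
        def its1_seqs(group_filter) -> list[tuple[str, str]]:
            return [
                (rid, by_id[rid].seq[slice(*partitions[rid].its1)])
                for rid in partitions
                if group_filter(by_id[rid].group)
            ]

        indel_rows = []
        for name, flt in [
            ("AMPELOMYCES", lambda g: g == "AMPELOMYCES"),
            ("PUTATIVE+OUTGROUP", lambda g: g != "AMPELOMYCES"),
        ]:
            seqs = its1_seqs(flt)
            if len(seqs) < 2:
                continue
            aln = msa(seqs, cfg.align)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = count_indel_events(aln.rows)
            indel_rows.append([name, len(seqs), rep.I,
                               ";".join(map(str, rep.positional_profile))])
            counts[f"indels_{name}"] = rep.I
        save_rows("indels.tsv", indel_rows,
                  ("dataset", "n_seqs", "indel_events", "event_start_columns"))
        note(f"indel events: {indel_rows}")
    except Exception as exc:
        fail("indels", exc)

    # ---- proximal-stem hybridization -------------------------------------
    hybrid = {}
    try:
        rows = []
        for rid, part in partitions.items():
            hr = hybridize_stem(part, by_id[rid], window=cfg.stem_window)
            hybrid[rid] = hr
            stability = (
                flag_pseudogene_candidate(hr)
                if hr.pattern != "UNMODELABLE" else ""
            )
            rows.append([rid, by_id[rid].group, hr.pattern, hr.dG, hr.dH,
                         hr.free_nt_5_8S, hr.free_nt_28S, stability])
        save_rows("hybridization.tsv", rows,
                  ("id", "group", "pattern", "dG", "dH", "free_5_8S",
                   "free_28S", "stability"),
                  decimals=[None, None, None, 2, 2, None, None, None])
        pats = [h.pattern for h in hybrid.values()]
        counts["stem_typical"] = pats.count("TYPICAL")
        counts["stem_variant"] = pats.count("VARIANT_MULTI_FREE")
        counts["stem_unmodelable"] = pats.count("UNMODELABLE")
        note(
            f"proximal stems: {counts['stem_typical']} typical, "
            f"{counts['stem_variant']} variant, "
            f"{counts['stem_unmodelable']} unmodelable"
        )
    except Exception as exc:
        fail("hybridization", exc)

    # ---- folding and model classification --------------------------------
    folded = {}
    models: dict[str, str] = {}
    try:
        rows = []
        for rid, part in partitions.items():
            its2 = by_id[rid].seq[slice(*part.its2)]
            if len(its2) < 50:
                models[rid] = "UNCLASSIFIED"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ss = fold_mfe(its2)
            hs = decompose_helices(ss)
            if hs.is_four:
                label = classify_model(hs, detect_motifs(hs))
                models[rid] = label.label
                evidence = "; ".join(label.evidence)
            else:
                models[rid] = "UNCLASSIFIED"
                evidence = f"{hs.n_top} top-level stems"
            folded[rid] = ss
            rows.append([rid, by_id[rid].group, ss.mfe, models[rid],
                         ss.structure, evidence])
        save_rows("structures.tsv", rows,
                  ("id", "group", "mfe", "model", "dot_bracket", "evidence"),
                  decimals=[None, None, 2, None, None, None])
        classified = sum(1 for m in models.values() if m != "UNCLASSIFIED")
        counts["folded"] = len(folded)
        counts["classified"] = classified
        note(f"folded {len(folded)} ITS2s; {classified} classified into models")
    except Exception as exc:
        fail("folding", exc)

    # ---- sequence-structure alignment + distances + trees ----------------
    gap_flag = None
    try:
        subset = _stratified_subset(records, models, manifest, cfg.max_phylo_taxa)
        subset = [rid for rid in subset if rid in folded]
        labels = {rid: by_id[rid].group for rid in subset}
        encoded = [
            (rid, encode_seqstruct(folded[rid].seq, folded[rid].structure))
            for rid in subset
        ]
        ss_aln = seqstruct_align(encoded, cfg.ss_align)
        from .seqstruct_phylo import decode_seqstruct

        dna_rows = []
        db_rows = []
        for row in ss_aln.rows:
            s, d = decode_seqstruct(row)
            dna_rows.append(s.replace("U", "T"))
            db_rows.append(d)
        dna_aln = Alignment(ids=list(ss_aln.ids), rows=dna_rows)
        with (out / "seqstruct_alignment.fasta").open("w") as fh:
            for i, (rid, row) in enumerate(zip(dna_aln.ids, dna_aln.rows)):
                fh.write(f">{rid}\n{row}\n")
        artifacts["seqstruct_alignment.fasta"] = str(out / "seqstruct_alignment.fasta")
        with (out / "seqstruct_alignment.dbn").open("w") as fh:
            for rid, row in zip(ss_aln.ids, db_rows):
                fh.write(f">{rid}\n{row}\n")
        artifacts["seqstruct_alignment.dbn"] = str(out / "seqstruct_alignment.dbn")

        dm, gap = group_mean_distances(
            dna_aln, labels, method="logdet", rate=cfg.rate,
            bootstrap_reps=cfg.bootstrap_reps, seed=_seed(cfg.master_seed, 1),
        )
        save_rows(
            "distances_between_groups_seqstruct.tsv",
            gap.between.values.tolist(), list(gap.between.columns),
            decimals={"mean": 4, "se": 4},
        )
        mat_rows = [
            [dm.ids[i]] + [f"{v:.4f}" if math.isfinite(v) else "SAT"
                           for v in dm.matrix[i]]
            for i in range(len(dm.ids))
        ]
        save_rows("distances_seqstruct.tsv", mat_rows, ["id"] + dm.ids)
        gap_flag = gap.barcode_gap
        gap_rows = [
            ["max_intra", g, f"{v:.4f}"] for g, v in gap.max_intra.items()
        ] + [
            ["min_inter", "all", f"{gap.min_inter:.4f}"],
            ["barcode_gap", "all", str(gap.barcode_gap)],
        ]
        save_rows("gap_report.tsv", gap_rows, ("quantity", "group", "value"))
        note(f"barcode gap (sequence-structure distances): {gap.barcode_gap}")

        tree = nj_bootstrap(
            dna_aln, method="logdet", rate=cfg.rate, reps=cfg.bootstrap_reps,
            seed=_seed(cfg.master_seed, 2), labels=labels,
        )
        ll = optimize_branch_lengths(tree, dna_aln, cfg.rate, sweeps=1)
        alpha_hat = estimate_gamma_shape(tree, dna_aln, cfg.rate)
        result.log_likelihoods["seqstruct"] = ll
        (out / "tree_seqstruct.nwk").write_text(tree.newick() + "\n")
        artifacts["tree_seqstruct.nwk"] = str(out / "tree_seqstruct.nwk")
        note(f"sequence-structure NJ tree logL={ll:.2f}, gamma shape~{alpha_hat:.2f}")

        # ITS-region tree on the same subset.
        its_aln = msa(
            [(rid, by_id[rid].seq[slice(partitions[rid].its_span[0],
                                        partitions[rid].its_span[1])])
             for rid in subset],
            cfg.align,
        )
        dm2, gap2 = group_mean_distances(
            its_aln, labels, method="logdet", rate=cfg.rate,
            bootstrap_reps=cfg.bootstrap_reps, seed=_seed(cfg.master_seed, 3),
        )
        save_rows(
            "distances_between_groups_its.tsv",
            gap2.between.values.tolist(), list(gap2.between.columns),
            decimals={"mean": 4, "se": 4},
        )
        tree2 = nj_bootstrap(
            its_aln, method="logdet", rate=cfg.rate, reps=cfg.bootstrap_reps,
            seed=_seed(cfg.master_seed, 4), labels=labels,
        )
        rate_its = RateModel(model="TN93", alpha=cfg.rate.alpha,
                             categories=cfg.rate.categories)
        ll2 = optimize_branch_lengths(tree2, its_aln, rate_its, sweeps=1)
        result.log_likelihoods["its"] = ll2
        (out / "tree_its.nwk").write_text(tree2.newick() + "\n")
        artifacts["tree_its.nwk"] = str(out / "tree_its.nwk")
        note(f"ITS-region NJ tree logL={ll2:.2f}")

        # Consensus structures per group (both gap policies).
        for g in group_names:
            rows_g = [
                (dna_rows[i], db_rows[i])
                for i, rid in enumerate(ss_aln.ids) if labels.get(rid) == g
            ]
            if not rows_g:
                continue
            text = []
            for policy in ("keep", "drop"):
                cons = consensus_structure(rows_g, gap_policy=policy)
                text.append(f"# gap policy: {policy}")
                text.append(cons.sequence)
                text.append(cons.structure)
                text.append(
                    " ".join(f"{c:.2f}" for c in cons.conservation)
                )
            path = out / f"consensus_{g}.txt"
            path.write_text("\n".join(text) + "\n")
            artifacts[path.name] = str(path)
        note("wrote consensus structures per group")
    except Exception as exc:
        fail("phylogenetics", exc)

    result.barcode_gap = gap_flag

    # ---- bundle metadata --------------------------------------------------
    params = {
        "version": __version__,
        "master_seed": cfg.master_seed,
        "bootstrap_reps": cfg.bootstrap_reps,
        "max_phylo_taxa": cfg.max_phylo_taxa,
        "stem_window": cfg.stem_window,
        "rate": {"model": cfg.rate.model, "alpha": cfg.rate.alpha,
                 "categories": cfg.rate.categories},
        "delimit": {
            "max_mismatches": cfg.delimit.max_mismatches,
            "evalue_threshold": cfg.delimit.evalue_threshold,
            "min_its2_len": cfg.delimit.min_its2_len,
            "max_its_len": cfg.delimit.max_its_len,
        },
        "counts": counts,
    }
    (out / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))
    artifacts["params.yaml"] = str(out / "params.yaml")
    (out / "run_log.txt").write_text("\n".join(run_log) + "\n")
    artifacts["run_log.txt"] = str(out / "run_log.txt")
    if errors:
        (out / "errors.json").write_text(json.dumps(errors, indent=2))
        artifacts["errors.json"] = str(out / "errors.json")
    return result
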