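"""Stage driver behind :func:`crcmb.core_io.run_pipeline`.

Each stage writes deterministic text outputs under the config's output
directory; every file header records the seed and the filter parameters, so
identical configs produce byte-identical statistical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import beta_diversity, diff_ranking, ordination, perm_stats, preprocess, survival_models
from .core_io import (
    CohortBundle,
    Config,
    read_feature_table,
    read_metadata,
    validate_cohort,
    write_feature_table,
    write_metadata,
)

_STAGE_DEPS = {
    "validate": (),
    "preprocess": ("validate",),
    "betadiv": ("validate",),
    "ordinate": ("validate",),
    "dr": ("validate",),
    "index": ("validate", "ordinate", "dr"),
    "model": ("validate", "index"),
}


class _Context:
    def __init__(self, config: Config):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.bundle: CohortBundle | None = None
        self.artifacts: dict[str, object] = {}
        self.files: dict[str, list[str]] = {}

    def header(self, stage: str, **params) -> str:
        cfg = self.config
        parts = [f"stage={stage}", f"seed={cfg.seed}", f"min_depth={cfg.min_depth}"]
        parts += [f"{k}={v}" for k, v in sorted(params.items())]
        return "crcmb " + " ".join(parts)

    def record(self, stage: str, path: Path) -> None:
        self.files.setdefault(stage, []).append(str(path))


def run(config: Config, stages: list[str]) -> dict[str, list[str]]:
    needed: list[str] = []
    for stage in stages:
        for dep in _STAGE_DEPS[stage]:
            if dep not in needed and dep not in stages:
                raise ValueError(f"stage {stage!r} requires upstream stage {dep!r}")
        needed.append(stage)
    ctx = _Context(config)
    runners = {
        "validate": _stage_validate,
        "preprocess": _stage_preprocess,
        "betadiv": _stage_betadiv,
        "ordinate": _stage_ordinate,
        "dr": _stage_dr,
        "index": _stage_index,
        "model": _stage_model,
    }
    for stage in stages:
        runners[stage](ctx)
    return ctx.files


def _stage_validate(ctx: _Context) -> None:
    cfg = ctx.config
    table = read_feature_table(cfg.table, dialect=cfg.dialect)
    metadata = read_metadata(cfg.metadata)
    ctx.bundle = validate_cohort(table, metadata, min_depth=cfg.min_depth)
    head = ctx.header("validate")
    write_feature_table(ctx.bundle.table, ctx.out / "validated_table.tsv", header=head)
    write_metadata(ctx.bundle.metadata, ctx.out / "validated_metadata.tsv", header=head)
    with open(ctx.out / "validate_exclusions.tsv", "w") as fh:
        fh.write(f"# {head}\n")
        fh.write("reason\tn\tsamples\n")
        prov = ctx.bundle.provenance
        for reason, samples in sorted(prov["exclusions"].items()):
            fh.write(f"{reason}\t{len(samples)}\t{','.join(samples)}\n")
    for name in ("validated_table.tsv", "validated_metadata.tsv", "validate_exclusions.tsv"):
        ctx.record("validate", ctx.out / name)


def _require_bundle(ctx: _Context, stage: str) -> CohortBundle:
    if ctx.bundle is None:
        raise RuntimeError(f"stage {stage!r} requires the validate stage to have run")
    return ctx.bundle


def _stage_preprocess(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "preprocess")
    head = ctx.header(
        "preprocess",
        rarefaction_depth=cfg.rarefaction_depth,
        ctf_min_samples=cfg.ctf_min_samples,
        ctf_min_total=cfg.ctf_min_total,
    )
    rare = preprocess.rarefy(bundle.table, cfg.rarefaction_depth, seed=cfg.seed)
    write_feature_table(rare, ctx.out / "rarefied_table.tsv", header=head)
    ctf_table = preprocess.filter_ctf(bundle.table, cfg.ctf_min_samples, cfg.ctf_min_total)
    write_feature_table(ctf_table, ctx.out / "ctf_filtered_table.tsv", header=head)
    dr_table = preprocess.filter_dr(bundle.table, cfg.dr_rel_threshold, cfg.dr_min_frac)
    write_feature_table(dr_table, ctx.out / "dr_filtered_table.tsv", header=head)
    preprocess.clr(bundle.table).to_tsv(ctx.out / "clr.tsv", header=head)
    preprocess.rclr(bundle.table).to_tsv(ctx.out / "rclr.tsv", header=head)
    ctx.artifacts["rarefied"] = rare
    ctx.artifacts["ctf_table"] = ctf_table
    ctx.artifacts["dr_table"] = dr_table
    for name in ("rarefied_table.tsv", "ctf_filtered_table.tsv", "dr_filtered_table.tsv",
                 "clr.tsv", "rclr.tsv"):
        ctx.record("preprocess", ctx.out / name)


def _stage_betadiv(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "betadiv")
    head = ctx.header("betadiv", n_perm=cfg.n_perm, rarefaction_depth=cfg.rarefaction_depth)
    rare = ctx.artifacts.get("rarefied")
    if rare is None:
        rare = preprocess.rarefy(bundle.table, cfg.rarefaction_depth, seed=cfg.seed)
    results = []
    for metric, source in (
        ("bray_curtis", rare),
        ("jaccard_binary", rare),
        ("aitchison", bundle.table),
    ):
        dm = beta_diversity.distance_matrix(source, metric)
        dm.to_tsv(ctx.out / f"distance_{metric}.tsv", header=head)
        ctx.record("betadiv", ctx.out / f"distance_{metric}.tsv")
        meta = bundle.metadata.select_samples(list(dm.ids))
        paired = beta_diversity.paired_distances(dm, meta)
        with open(ctx.out / f"paired_{metric}.tsv", "w") as fh:
            fh.write(f"# {head}\n")
            fh.write("subject_id\tdistance\n")
            for subj, val in paired.items():
                fh.write(f"{subj}\t{val!r}\n")
        ctx.record("betadiv", ctx.out / f"paired_{metric}.tsv")
        strata = tuple(
            c for c in ("tissue", "location", "survival") if c in meta.frame.columns
        )
        res = beta_diversity.intra_inter_test(
            dm, meta, n_perm=cfg.n_perm, seed=cfg.seed, strata=strata
        )
        results.append(res)
    perm_stats.write_results(results, ctx.out / "betadiv_tests.tsv", header=head)
    ctx.record("betadiv", ctx.out / "betadiv_tests.tsv")


def _stage_ordinate(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "ordinate")
    head = ctx.header("ordinate", ctf_rank=cfg.ctf_rank, n_perm=cfg.n_perm)
    ctf_table = ctx.artifacts.get("ctf_table")
    if ctf_table is None:
        ctf_table = preprocess.filter_ctf(bundle.table, cfg.ctf_min_samples, cfg.ctf_min_total)
    result = ordination.ctf(ctf_table, bundle.metadata, k=cfg.ctf_rank, seed=cfg.seed)
    ctx.artifacts["ctf"] = result

    with open(ctx.out / "ctf_subject_scores.tsv", "w") as fh:
        fh.write(f"# {head}\n")
        fh.write("subject_id\t" + "\t".join(f"PC{i+1}" for i in range(result.rank)) + "\n")
        for subj, row in zip(result.subject_ids, result.subject_scores):
            fh.write(subj + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    ctx.record("ordinate", ctx.out / "ctf_subject_scores.tsv")

    deltas = ordination.paired_pc_deltas(result)
    with open(ctx.out / "ctf_pc_deltas.tsv", "w") as fh:
        fh.write(f"# {head}\n")
        fh.write("subject_id\t" + "\t".join(f"dPC{i+1}" for i in range(result.rank)) + "\n")
        for subj, row in deltas.items():
            fh.write(subj + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    ctx.record("ordinate", ctx.out / "ctf_pc_deltas.tsv")

    delta_mat = np.vstack(list(deltas.values()))
    tests = [
        perm_stats.perm_paired_t(delta_mat[:, i], n_perm=cfg.n_perm, seed=cfg.seed)
        for i in range(result.rank)
    ]
    survival = bundle.metadata.subject_survival().loc[list(deltas.keys())]
    for i in range(result.rank):
        tests.append(
            perm_stats.perm_welch_t(
                delta_mat[survival.to_numpy() == "short", i],
                delta_mat[survival.to_numpy() == "long", i],
                n_perm=cfg.n_perm,
                seed=cfg.seed,
            )
        )
    sd = ordination.subject_distance(result)
    tests.append(
        perm_stats.permanova(sd, survival.to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed)
    )
    perm_stats.write_results(tests, ctx.out / "ordinate_tests.tsv", header=head)
    ctx.record("ordinate", ctx.out / "ordinate_tests.tsv")

    # tumor-only rPCA with auto rank
    tumor_samples = [
        s for s in bundle.table.sample_ids
        if bundle.metadata.frame.loc[s, "tissue"] == "tumor"
    ]
    tumor_table = preprocess.filter_rpca(
        bundle.table.select_samples(tumor_samples), cfg.rpca_min_frac, cfg.rpca_min_total
    )
    rp = ordination.rpca(tumor_table, rank="auto", seed=cfg.seed)
    rp.to_txt(ctx.out / "rpca_tumor.txt", header=head)
    ctx.artifacts["rpca_tumor"] = rp
    ctx.artifacts["rpca_tumor_table"] = tumor_table
    ctx.record("ordinate", ctx.out / "rpca_tumor.txt")


def _stage_dr(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "dr")
    head = ctx.header("dr", iterations=cfg.dr_iterations, method=cfg.dr_method)
    dr_table = ctx.artifacts.get("dr_table")
    if dr_table is None:
        dr_table = preprocess.filter_dr(bundle.table, cfg.dr_rel_threshold, cfg.dr_min_frac)
    for design in ("tissue", "tissue_x_survival"):
        ranks = diff_ranking.fit_differentials(
            dr_table, bundle.metadata, design=design,
            iterations=cfg.dr_iterations, seed=cfg.seed, method=cfg.dr_method,
        )
        ranks.to_tsv(ctx.out / f"differentials_{design}.tsv", header=head)
        ctx.artifacts[f"ranks_{design}"] = ranks
        ctx.record("dr", ctx.out / f"differentials_{design}.tsv")
    ranks = ctx.artifacts["ranks_tissue"]
    for direction, tag in (("high", "tumor_associated"), ("low", "normal_associated")):
        cover = diff_ranking.select_extreme_cover(
            ranks, dr_table, bundle.metadata, contrast="tissue", direction=direction
        )
        cover.to_tsv(ctx.out / f"cover_{tag}.tsv", header=head)
        ctx.artifacts[f"cover_{tag}"] = cover
        ctx.record("dr", ctx.out / f"cover_{tag}.tsv")
    ctx.artifacts["dr_table_used"] = dr_table


def _stage_index(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "index")
    head = ctx.header("index")
    dr_table = ctx.artifacts["dr_table_used"]
    normal_cover = ctx.artifacts["cover_normal_associated"]
    tumor_cover = ctx.artifacts["cover_tumor_associated"]
    num = [f for f in normal_cover.features if f not in set(tumor_cover.features)]
    den = [f for f in tumor_cover.features if f not in set(normal_cover.features)]
    pooled = survival_models.compute_alr(dr_table, num, den)
    pooled.to_tsv(ctx.out / "alr_pooled.tsv", header=head)
    ctx.artifacts["alr_pooled"] = pooled
    ctx.record("index", ctx.out / "alr_pooled.tsv")

    rp = ctx.artifacts["rpca_tumor"]
    candidates = survival_models.communality_select(rp)
    upper, lower = survival_models.loading_quartile_sets(rp, 0, candidates)
    rpca_alr = survival_models.compute_alr(
        ctx.artifacts["rpca_tumor_table"], upper, lower
    )
    rpca_alr.to_tsv(ctx.out / "alr_rpca_pc1.tsv", header=head)
    ctx.artifacts["alr_rpca"] = rpca_alr
    ctx.record("index", ctx.out / "alr_rpca_pc1.tsv")


def _stage_model(ctx: _Context) -> None:
    cfg = ctx.config
    bundle = _require_bundle(ctx, "model")
    head = ctx.header("model")
    pooled = ctx.artifacts["alr_pooled"]
    lme = survival_models.lme_alr(pooled, bundle.metadata, design="tissue_x_survival")
    with open(ctx.out / "lme_alr.tsv", "w") as fh:
        fh.write(f"# {head}\n")
        lme.coefficients.rename_axis("term").reset_index().to_csv(fh, sep="\t", index=False)
    ctx.record("model", ctx.out / "lme_alr.tsv")

    rpca_alr = ctx.artifacts["alr_rpca"]
    frame = bundle.metadata.frame
    subj_of = frame.loc[list(rpca_alr.sample_ids), "subject_id"]
    per_subject = pd.Series(rpca_alr.values, index=subj_of.to_numpy())
    rows = []
    for adjust in (False, True):
        try:
            res = survival_models.logistic_survival(per_subject, bundle.metadata, adjust=adjust)
        except (survival_models.PerfectSeparationError, ValueError) as exc:
            rows.append({"model": "adjusted" if adjust else "crude", "error": str(exc)})
            continue
        for term, vals in res.terms.iterrows():
            rows.append({"model": res.model, "term": term, **vals.to_dict()})
    with open(ctx.out / "logistic_survival.tsv", "w") as fh:
        fh.write(f"# {head}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    ctx.record("model", ctx.out / "logistic_survival.tsv")
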