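"""End-to-end driver: simulate -> map -> call -> cluster -> annotate -> enrich.

Runs the whole analysis on a synthetic study and writes the analogue of each
published supplementary table plus a machine-readable run manifest. Every
tabular output carries a header comment with the seed and a hash of the
configuration, so a run can be traced back to its exact parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np

from . import __version__
from .core import MITOCHONDRIAL, RNA_BASES, Transcript
from .synthetic import (
    PlantedEvent,
    SyntheticConfig,
    generate_go_map,
    generate_transcriptome,
    plant_events,
    simulate_mpss_library,
)
from .mapping import OneMismatchIndex, map_library
from .calling import (
    CallingCriteria,
    aggregate_sites,
    apply_criteria,
    classify_targets,
    compute_editing_ratios,
)
from .tissue import build_ratio_matrix, cluster_sites, filter_for_clustering
from .annotation import (
    annotate_boundaries,
    annotate_codon_effect,
    summarize_codon_table,
)
from .context import extract_windows, position_information
from .enrichment import flag_significant, hypergeom_enrich
from . import io as eio

logger = logging.getLogger("editscan.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic run."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    criteria: CallingCriteria = dataclasses.field(default_factory=CallingCriteria)
    cluster_threshold: float = 0.02
    cluster_mode: str = "any"
    flank: int = 50
    alpha: float = 1.0e-7
    # planted-truth design
    edited_fraction: float = 0.5
    sites_per_transcript: int = 3
    ratio_range: tuple[float, float] = (0.2, 0.8)
    tissue_specific_fraction: float = 0.2

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        syn = data.pop("synthetic", {})
        crit = data.pop("criteria", {})
        cfg = cls(**data)
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        if crit:
            cfg.criteria = CallingCriteria(**crit)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def design_events(
    transcripts: list[Transcript], config: PipelineConfig
) -> list[PlantedEvent]:
    """Draw a ground-truth editing design for the synthetic study.

    Edited transcripts receive ``sites_per_transcript`` sites inside their
    CDS; mitochondrial transcripts are edited C-to-U only, nuclear ones with
    random patterns. A fraction of edited transcripts are tissue-specific
    (edited in a single library).
    """
    rng = np.random.default_rng([config.synthetic.seed, 0xED])
    libs = config.synthetic.library_ids
    events: list[PlantedEvent] = []
    L = config.synthetic.tag_length
    for tx in transcripts:
        if rng.random() > config.edited_fraction or tx.cds is None:
            continue
        lo = max(tx.cds[0], L + 1)
        hi = min(tx.cds[1], len(tx.sequence) - L)
        if hi - lo < 3 * config.sites_per_transcript:
            continue
        positions = sorted(
            int(p)
            for p in rng.choice(
                np.arange(lo, hi + 1), size=config.sites_per_transcript, replace=False
            )
        )
        tissue_specific = rng.random() < config.tissue_specific_fraction
        target_lib = str(rng.choice(libs)) if tissue_specific else None
        for pos in positions:
            ref = tx.base_at(pos)
            if tx.compartment == MITOCHONDRIAL and ref == "C":
                to = "U"
            else:
                to = str(rng.choice([b for b in RNA_BASES if b != ref]))
            ratio = float(rng.uniform(*config.ratio_range))
            if target_lib is not None:
                ratios = {lib: (ratio if lib == target_lib else 0.0) for lib in libs}
            else:
                ratios = {lib: ratio for lib in libs}
            events.append(PlantedEvent(tx.id, pos, ref, to, ratios))
    return events


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"editscan v{__version__} seed={config.synthetic.seed} config={config.config_hash}"
    report: dict = {"version": __version__, "seed": config.synthetic.seed,
                    "config_hash": config.config_hash, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    syn = config.synthetic
    transcripts, premirnas = generate_transcriptome(syn)
    events = design_events(transcripts, config)
    hapsets = plant_events(transcripts, events)
    eio.write_fasta({t.id: t.sequence for t in transcripts}, out / "transcripts.fasta")
    eio.write_gff3(transcripts, out / "transcripts.gff3", header=tag)
    eio.write_premirna_fasta(premirnas, out / "premirnas.fasta")
    eio.write_events_tsv(events, out / "truth_events.tsv", syn.library_ids, header=tag)
    libdir = out / "libraries"
    libdir.mkdir(exist_ok=True)
    seeds = np.random.SeedSequence(syn.seed).spawn(syn.n_libraries)
    libraries = []
    for lib_id, ss in zip(syn.library_ids, seeds):
        lib = simulate_mpss_library(
            hapsets, syn, lib_id, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        libraries.append(lib)
        eio.write_tag_tsv(lib, libdir / f"{lib_id}.tsv", header=tag)
    report["stages"]["simulate"] = {
        "n_transcripts": len(transcripts),
        "n_premirnas": len(premirnas),
        "n_planted_events": len(events),
        "n_libraries": len(libraries),
        "tags_per_library": [lib.total_count for lib in libraries],
    }

    # --- map ----------------------------------------------------------------
    stage("map")
    targets = {t.id: t.sequence for t in transcripts}
    targets.update({p.id: p.sequence for p in premirnas})
    index = OneMismatchIndex(targets, syn.tag_length)
    map_results = [map_library(lib, index) for lib in libraries]
    all_mismatches = [r for res in map_results for r in res.mismatches]
    eio.write_mismatch_tsv(all_mismatches, out / "mismatches.tsv", header=tag)
    report["stages"]["map"] = {
        "n_mismatch_records": len(all_mismatches),
        "n_perfect": sum(len(res.perfect) for res in map_results),
        "n_ambiguous": sum(len(res.ambiguous) for res in map_results),
        "n_unmapped": sum(len(res.unmapped) for res in map_results),
    }

    # --- call ---------------------------------------------------------------
    stage("call")
    classes = classify_targets(transcripts, premirnas)
    candidates = aggregate_sites(all_mismatches, classes)
    called = apply_criteria(candidates, config.criteria)
    called = compute_editing_ratios(called, map_results)
    eio.write_sites_tsv(called, out / "sites.tsv", syn.library_ids, header=tag)
    eio.write_bed(called, out / "sites.bed", header=tag)
    report["stages"]["call"] = {
        "n_candidate_sites": len(candidates),
        "n_called_sites": len(called),
        "n_edited_transcripts": len({s.target_id for s in called}),
    }

    # --- cluster ------------------------------------------------------------
    stage("cluster")
    matrix = build_ratio_matrix(called, syn.library_ids)
    filtered = filter_for_clustering(matrix, config.cluster_threshold, config.cluster_mode)
    cluster_info: dict = {"n_rows_after_filter": int(len(filtered))}
    if len(filtered) >= 2:
        result = cluster_sites(filtered)
        ordered = result.ordered_matrix
        with open(out / "cluster_matrix.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            ordered.to_csv(fh, sep="\t", na_rep="NA")
        (out / "cluster_tree.newick").write_text(result.newick + "\n")
        cluster_info["leaf_order"] = result.leaf_order
    report["stages"]["cluster"] = cluster_info

    # --- annotate -----------------------------------------------------------
    stage("annotate")
    tx_by_id = {t.id: t for t in transcripts}
    effects = []
    boundary_lines = ["site_id\texon_index\twithin_first3\twithin_last3\tdist_to_cds_end"]
    for site in called:
        tx = tx_by_id.get(site.target_id)
        if tx is None:
            continue
        try:
            eff = annotate_codon_effect(site, tx)
        except ValueError:
            logger.warning("skipping codon annotation for %s", site.site_id)
            eff = None
        if eff is not None:
            effects.append(eff)
        try:
            b = annotate_boundaries(site, tx)
            boundary_lines.append(
                f"{site.site_id}\t{b.exon_index}\t{b.within_first3}"
                f"\t{b.within_last3}\t{b.distance_to_cds_end}"
            )
        except ValueError:
            pass
    table = summarize_codon_table(effects)
    with open(out / "codon_table.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        table.to_csv(fh, sep="\t")
    effect_lines = [
        "site_id\tcodon_before\tcodon_after\taa_before\taa_after"
        "\tcreates_start\tcreates_stop"
    ]
    for e in effects:
        effect_lines.append(
            f"{e.target_id}:{e.position}:{e.pattern}\t{e.codon_before}\t{e.codon_after}"
            f"\t{e.amino_acid_before}\t{e.amino_acid_after}"
            f"\t{e.creates_start}\t{e.creates_stop}"
        )
    (out / "codon_effects.tsv").write_text(
        f"# {tag}\n" + "\n".join(effect_lines) + "\n"
    )
    (out / "boundaries.tsv").write_text(
        f"# {tag}\n" + "\n".join(boundary_lines) + "\n"
    )
    report["stages"]["annotate"] = {
        "n_codon_effects": len(effects),
        "n_new_start": sum(e.creates_start for e in effects),
        "n_new_stop": sum(e.creates_stop for e in effects),
    }

    # --- context ------------------------------------------------------------
    stage("context")
    by_pattern: dict[str, list] = defaultdict(list)
    for site in called:
        if site.target_id in tx_by_id:
            by_pattern[site.pattern].append(site)
    ic_lines = ["pattern\toffset\tA\tC\tG\tU\tic_bits\tn"]
    window_fasta: dict[str, str] = {}
    for pattern in sorted(by_pattern):
        sites_p = by_pattern[pattern]
        windows = extract_windows(sites_p, tx_by_id, flank=config.flank)
        for site, w in zip(sites_p, windows):
            window_fasta[f"{site.site_id}"] = w.replace("N", "")
        cm = position_information(windows, pattern=pattern)
        for j, off in enumerate(cm.offsets):
            fr = cm.base_frequencies.iloc[:, j]
            ic = cm.information_content[j]
            ic_lines.append(
                f"{pattern}\t{off}\t{fr['A']:.4f}\t{fr['C']:.4f}\t{fr['G']:.4f}"
                f"\t{fr['U']:.4f}\t{'NA' if np.isnan(ic) else f'{ic:.4f}'}"
                f"\t{cm.n_sequences}"
            )
    if window_fasta:
        eio.write_fasta(window_fasta, out / "context_windows.fasta")
    (out / "context_ic.tsv").write_text(f"# {tag}\n" + "\n".join(ic_lines) + "\n")
    report["stages"]["context"] = {"n_patterns": len(by_pattern)}

    # --- enrich -------------------------------------------------------------
    stage("enrich")
    background = [t.id for t in transcripts]
    go_map = generate_go_map(background, seed=syn.seed)
    eio.write_go_tsv(go_map, out / "go_map.tsv")
    edited_genes = sorted(
        {s.target_id for s in called if s.target_id in tx_by_id}
    )
    enrich_lines = [
        "term_id\tn_background\tn_bg_with_term\tn_edited\tn_edited_with_term"
        "\tpct_all\tpct_edited\tp_raw\tp_corrected\tsignificant"
    ]
    n_significant = 0
    if edited_genes:
        results = hypergeom_enrich(edited_genes, background, go_map)
        significant = {r.term_id for r in flag_significant(results, config.alpha)}
        n_significant = len(significant)
        for r in results:
            enrich_lines.append(
                f"{r.term_id}\t{r.n_background}\t{r.n_background_with_term}"
                f"\t{r.n_edited}\t{r.n_edited_with_term}\t{r.pct_all:.4f}"
                f"\t{r.pct_edited:.4f}\t{r.p_raw:.3e}\t{r.p_corrected:.3e}"
                f"\t{r.term_id in significant}"
            )
    (out / "enrichment.tsv").write_text(f"# {tag}\n" + "\n".join(enrich_lines) + "\n")
    report["stages"]["enrich"] = {
        "n_edited_genes": len(edited_genes),
        "n_significant_terms": n_significant,
    }

    (out / "manifest.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
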