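"""End-to-end demonstration pipeline on simulated data.

``run_demo`` chains simulate -> OCI -> TADs -> interaction matrices ->
HMM domains -> clustering from a single seed, writes every table with a
provenance header, and scores the calls against the planted truth
(sensitivity/FDR of opening-TAD calls, sign accuracy of delta-OCI,
identity of the interaction-matrix maximum).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import write_coo
from .domains import cluster_oci, decode_domains, domain_conservation, fit_hmm
from .enrichment import histone_domain_change, interaction_change
from .genome import IntervalSet, write_bed
from .oci import OCIParams, compute_oci, delta_oci, stratify_oci
from .simulate import SimulationConfig, emit_truth, plan_genome, simulate_condition
from .tads import (
    boundary_conservation,
    call_tads,
    compare_tads,
    directionality_index,
    tad_feature_enrichment,
)

__all__ = ["run_demo", "truth_report"]


def _write_table(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def truth_report(
    genome,
    truth,
    tad_table: pd.DataFrame,
    d_oci,
    change_matrix: pd.DataFrame,
) -> dict:
    """Score pipeline calls against the planted simulation truth."""
    cfg = genome.config
    # opening-TAD calls vs planted opening flags, matched by interval midpoints
    planted = truth.per_tad
    opened = tad_table["label"] == "opening"
    mids_called = (tad_table["start"] + tad_table["end"]) / 2
    planted_open = []
    for chrom, mid in zip(tad_table["chrom"], mids_called):
        sub = planted[(planted["chrom"] == chrom)
                      & (planted["start"] <= mid) & (mid < planted["end"])]
        planted_open.append(bool(sub["opening"].any()) if len(sub) else False)
    planted_open = np.asarray(planted_open)
    n_planted = int(planted["opening"].sum())
    tp = int((opened & planted_open).sum())
    fp = int((opened & ~planted_open).sum())
    sensitivity = (
        tp / int(planted_open.sum()) if planted_open.any() else float("nan")
    )
    fdr = fp / max(tp + fp, 1)

    # delta-OCI sign accuracy over planted "+" windows (windows == bins here)
    plus = truth.per_bin["delta_oci_dir"].to_numpy() == "+"
    ok = ~np.isnan(d_oci.values)
    sel = plus & ok
    sign_acc = float((d_oci.values[sel] > 0).mean()) if sel.any() else float("nan")

    # interaction-change maximum should be target-class x target-class
    m = change_matrix.to_numpy()
    i, j = np.unravel_index(np.nanargmax(m), m.shape)
    max_pair = (change_matrix.index[i], change_matrix.columns[j])
    return {
        "n_planted_opening_tads": n_planted,
        "opening_sensitivity": sensitivity,
        "opening_fdr": fdr,
        "n_opening_calls": int(opened.sum()),
        "delta_oci_sign_accuracy_target": sign_acc,
        "n_target_windows": int(sel.sum()),
        "interaction_change_max_pair": list(max_pair),
        "interaction_change_max_value": float(m[i, j]),
        "max_pair_is_target": max_pair == (cfg.target_class, cfg.target_class),
    }


def run_demo(config: SimulationConfig, outdir, oci_params: OCIParams | None = None) -> dict:
    """Run the full synthetic-data demonstration; returns the truth report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = oci_params or OCIParams(window_bp=config.bin_size)
    header = {
        "tool": f"chromoci {__version__}",
        "seed": config.seed,
        "config": json.dumps(config.as_dict()),
    }

    genome = plan_genome(config)
    truth = emit_truth(genome)
    maps = {c: simulate_condition(genome, c) for c in ("growing", "senescent", "esc")}
    for cond, cmap in maps.items():
        write_coo(cmap, out / f"map_{cond}.coo.tsv", out / "bins.tsv")
    for name, ivs in [
        ("isochores", genome.isochores), ("lads", genome.lads),
        ("tads_planted", genome.tads), ("histone_marks", genome.histone_domains),
    ]:
        write_bed(ivs, out / f"{name}.bed")
    _write_table(truth.per_bin, out / "truth_bins.tsv", header)
    _write_table(truth.per_tad, out / "truth_tads.tsv", header)
    with open(out / "config.txt", "w") as fh:
        for key, val in config.as_dict().items():
            fh.write(f"{key}={val}\n")

    # --- OCI ---------------------------------------------------------------
    tracks = {c: compute_oci(m, params) for c, m in maps.items()}
    for cond, tr in tracks.items():
        _write_table(tr.frame(), out / f"oci_{cond}.tsv", header)
    d = delta_oci(tracks["growing"], tracks["senescent"])
    _write_table(
        pd.DataFrame({
            "chrom": d.bins.chrom, "start": d.bins.start, "end": d.bins.end,
            "delta_oci": d.values,
        }),
        out / "delta_oci.tsv", header,
    )
    strat = stratify_oci(d, genome.bin_class)
    _write_table(strat, out / "delta_oci_by_class.tsv", header)

    # --- TADs --------------------------------------------------------------
    di = directionality_index(maps["growing"])
    called = call_tads(di)
    write_bed(called, out / "tads_called.bed")
    table = compare_tads(called, maps["growing"], maps["senescent"])
    _write_table(table, out / "tad_comparison.tsv", header)
    di_s = directionality_index(maps["senescent"])
    cons = boundary_conservation(
        called, call_tads(di_s), genome.bins.bin_size
    )
    opening = called.frame.index[table["label"] == "opening"]
    selection = IntervalSet("opening_tads", called.frame.loc[opening])
    enr = tad_feature_enrichment(
        selection, {"LADs": genome.lads, "L1_isochores": genome.isochores.subset("L1")},
        genome.assembly,
    ) if len(selection) else pd.DataFrame()
    if len(enr):
        _write_table(enr, out / "opening_tad_enrichment.tsv", header)

    # --- interaction-change matrices ----------------------------------------
    change = interaction_change(maps["growing"], maps["senescent"], genome.bin_class)
    change.rename_axis("class").reset_index().to_csv(
        out / "interaction_change_isochore_lad.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    hist = histone_domain_change(
        maps["growing"], maps["senescent"],
        {m: genome.histone_domains.subset(m) for m in genome.histone_domains.labels},
    )
    hist.rename_axis("mark").reset_index().to_csv(
        out / "interaction_change_histone.tsv", sep="\t", index=False,
        float_format="%.6g",
    )

    # --- HMM domains and conservation ---------------------------------------
    model = fit_hmm(tracks["esc"], seed=config.seed)
    esc_domains = decode_domains(model, tracks["esc"])
    write_bed(esc_domains, out / "oci_domains_esc.bed")
    cons_rows = []
    for cond in ("esc", "growing", "senescent"):
        ct = domain_conservation(esc_domains, tracks[cond], model)
        ct.insert(0, "condition", cond)
        cons_rows.append(ct)
    _write_table(pd.concat(cons_rows, ignore_index=True),
                 out / "domain_conservation.tsv", header)

    # --- clustering ----------------------------------------------------------
    window_bp = max(1_000_000, params.window_bp)
    clus = cluster_oci(
        {c: tracks[c] for c in ("growing", "senescent", "esc")},
        window_bp=window_bp, k=6, gc=genome.gc,
    )
    _write_table(clus.cluster_means, out / "oci_clusters.tsv", header)

    # --- truth comparison -----------------------------------------------------
    report = truth_report(genome, truth, table, d, change)
    report["tad_boundary_conservation_a_in_b"] = cons["a_in_b"]
    report["hmm_means"] = [float(x) for x in model.means]
    with open(out / "truth_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
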