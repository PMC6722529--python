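"""One-command reproduction of the full codon-usage analysis suite.

``run_all`` takes a FASTA + optional metadata TSV + one or more host
codon-usage tables and emits every plot-ready table the analyses produce:
composition, RSCU, ENC (per-sequence and ENC-GC3s plot data), PR2,
neutrality fits (overall and per host), CAI/RCDI, SiD, PCA inertia and
scores, and the GRAVY/ARO correlation matrix, plus a JSON manifest and a
deterministic run log. The pipeline adds no computation of its own: every
number in the tables is reproducible by calling the module operations
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .adaptation import (
    HostUsageTable,
    SiDConvention,
    adaptation_scores,
    load_host_table,
)
from .composition import composition_table, group_summary
from .enc import enc_plot_table
from .multivariate import inertia_table, pca_rscu
from .rscu import mean_rscu, rscu, rscu_table
from .selection import PR2Mode, correlation_matrix, neutrality_fit, pr2_point
from .seq_io import (
    attach_metadata,
    count_codons,
    read_fasta,
    read_metadata,
)

FLOAT_FMT = "%.4f"

#: the core output files every complete run emits
CORE_OUTPUTS = (
    "composition.tsv",
    "rscu_table1.tsv",
    "enc.tsv",
    "enc_plot.tsv",
    "pr2.tsv",
    "neutrality.tsv",
    "cai_rcdi.tsv",
    "sid.tsv",
    "pca_inertia.tsv",
    "pca_scores.tsv",
    "correlations_table2.tsv",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    fasta: str | Path
    out_dir: str | Path
    meta: str | Path | None = None
    host_tables: Sequence[str | Path] = ()
    host_table_format: str = "kazusa"
    grouping: str = "host"
    rscu_over: float = 1.6
    rscu_under: float = 0.6
    enc_bias_threshold: float = 35.0
    pr2_mode: PR2Mode = "strict4"
    sid_convention: SiDConvention = "half-diff"
    seed: int = 0

    def __post_init__(self):
        if self.rscu_over <= 0 or self.rscu_under <= 0:
            raise ValueError("RSCU thresholds must be positive")
        if self.enc_bias_threshold <= 0:
            raise ValueError("ENC bias threshold must be positive")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # paths are echoed by basename only so identical runs in different
    # directories produce byte-identical manifests and logs
    config_echo: dict[str, str] = {}
    for key, value in asdict(config).items():
        if key == "out_dir":
            config_echo[key] = "."  # never echo the output location itself
        elif key in ("fasta", "meta"):
            config_echo[key] = Path(value).name if value else ""
        elif key == "host_tables":
            config_echo[key] = ",".join(Path(p).name for p in value)
        else:
            config_echo[key] = str(value)
    log_lines: list[str] = [
        f"codonuse {__version__}",
        f"config: {json.dumps(config_echo, sort_keys=True)}",
        f"seed: {config.seed}",
    ]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "stages": {},
        "outputs": [],
    }

    def stage(name: str, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
            log_lines.append(f"stage {name}: ok")
        except Exception as exc:  # noqa: BLE001 -- logged and re-raised
            manifest["stages"][name] = f"failed: {exc}"
            log_lines.append(f"stage {name}: FAILED: {exc}")
            _finish(out, manifest, log_lines)
            raise

    # --- load inputs -------------------------------------------------
    seqs: list = []
    hosts: list[HostUsageTable] = []

    def load():
        nonlocal seqs, hosts
        seqs = read_fasta(config.fasta)
        if config.meta:
            seqs = attach_metadata(seqs, read_metadata(config.meta))
        hosts = [
            load_host_table(p, fmt=config.host_table_format)
            for p in config.host_tables
        ]
        log_lines.append(f"loaded {len(seqs)} sequences, {len(hosts)} hosts")

    stage("load", load)

    counts = [count_codons(s, exclude_nonbias=True) for s in seqs]
    vectors = [rscu(c) for c in counts]
    ids = [s.id for s in seqs]
    comp = composition_table(seqs)

    # --- composition -------------------------------------------------
    def do_composition():
        _write(comp, out / "composition.tsv")
        manifest["outputs"].append("composition.tsv")

    stage("composition", do_composition)

    # --- RSCU table --------------------------------------------------
    def do_rscu():
        groups = {"All": mean_rscu(vectors)}
        labels = comp[config.grouping] if config.grouping in comp else None
        if labels is not None and labels.notna().any():
            for label in sorted(labels.dropna().unique()):
                members = [
                    v for v, keep in zip(vectors, labels == label) if keep
                ]
                if members:
                    groups[str(label)] = mean_rscu(members)
        _write(rscu_table(groups), out / "rscu_table1.tsv")
        manifest["outputs"].append("rscu_table1.tsv")

    stage("rscu", do_rscu)

    # --- ENC ----------------------------------------------------------
    plot = enc_plot_table(seqs)

    def do_enc():
        enc_cols = plot[
            ["id", "host", "group", "enc", "gc3s", "significant_bias"]
        ].copy()
        enc_cols["gc3s"] = 100.0 * enc_cols["gc3s"]
        _write(enc_cols, out / "enc.tsv")
        _write(plot, out / "enc_plot.tsv")
        summary = group_summary(
            plot[["host", "enc", "gc3s"]].dropna(subset=["host"]), by="host"
        ).reset_index()
        _write(summary, out / "enc_summary.tsv")
        manifest["outputs"] += ["enc.tsv", "enc_plot.tsv", "enc_summary.tsv"]

    stage("enc", do_enc)

    # --- PR2 ----------------------------------------------------------
    def do_pr2():
        rows = []
        for s, c in zip(seqs, counts):
            p = pr2_point(c, mode=config.pr2_mode)
            rows.append(
                {
                    "id": s.id,
                    "host": s.host,
                    "group": s.group,
                    "at_bias": p.at_bias,
                    "gc_bias": p.gc_bias,
                    "n_codons": p.n_codons,
                }
            )
        _write(pd.DataFrame(rows), out / "pr2.tsv")
        manifest["outputs"].append("pr2.tsv")

    stage("pr2", do_pr2)

    # --- neutrality ----------------------------------------------------
    def do_neutrality():
        rows = []

        def add(label: str, sub: pd.DataFrame):
            try:
                fit = neutrality_fit(sub["gc12s"], sub["gc3s"])
            except ValueError as exc:
                rows.append({"subset": label, "n": len(sub), "error": str(exc)})
                return
            rows.append(
                {
                    "subset": label,
                    "n": fit.n,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "pvalue": fit.pvalue,
                    "mutation_pct": fit.mutation_pct,
                    "selection_pct": fit.selection_pct,
                    "slope_raw": repr(fit.slope),
                    "pvalue_raw": repr(fit.pvalue),
                }
            )

        add("all", comp)
        if comp["host"].notna().any():
            for label in sorted(comp["host"].dropna().unique()):
                add(str(label), comp[comp["host"] == label])
        _write(pd.DataFrame(rows), out / "neutrality.tsv")
        manifest["outputs"].append("neutrality.tsv")

    stage("neutrality", do_neutrality)

    # --- PCA -----------------------------------------------------------
    pca = pca_rscu(vectors, ids=ids, n_axes=4)

    def do_pca():
        tab = inertia_table(pca)
        tab["inertia_raw"] = [repr(v) for v in pca.inertia]
        _write(tab, out / "pca_inertia.tsv")
        scores = pca.scores.reset_index(names="id")
        scores.insert(1, "host", comp["host"].values)
        scores.insert(2, "group", comp["group"].values)
        _write(scores, out / "pca_scores.tsv")
        manifest["outputs"] += ["pca_inertia.tsv", "pca_scores.tsv"]

    stage("pca", do_pca)

    # --- adaptation ------------------------------------------------------
    def do_adaptation():
        cai_rows, sid_rows = [], []
        for s, c, v in zip(seqs, counts, vectors):
            for host in hosts:
                sc = adaptation_scores(
                    c, v, host, convention=config.sid_convention
                )
                cai_rows.append(
                    {
                        "id": s.id,
                        "host": s.host,
                        "host_table": host.name,
                        "cai": sc.cai,
                        "rcdi": sc.rcdi,
                    }
                )
                sid_rows.append(
                    {
                        "id": s.id,
                        "host": s.host,
                        "host_table": host.name,
                        "r_cos": sc.r_cos,
                        "sid": sc.sid,
                    }
                )
        _write(pd.DataFrame(cai_rows), out / "cai_rcdi.tsv")
        _write(pd.DataFrame(sid_rows), out / "sid.tsv")
        manifest["outputs"] += ["cai_rcdi.tsv", "sid.tsv"]

    if hosts:
        stage("adaptation", do_adaptation)
    else:
        # still emit the (empty) tables so the output contract holds
        _write(
            pd.DataFrame(columns=["id", "host", "host_table", "cai", "rcdi"]),
            out / "cai_rcdi.tsv",
        )
        _write(
            pd.DataFrame(columns=["id", "host", "host_table", "r_cos", "sid"]),
            out / "sid.tsv",
        )
        manifest["outputs"] += ["cai_rcdi.tsv", "sid.tsv"]
        manifest["stages"]["adaptation"] = "skipped: no host tables"
        log_lines.append("stage adaptation: skipped (no host tables)")

    # --- correlations ----------------------------------------------------
    def do_correlations():
        table = comp[["gravy", "aroma", "gc3s", "gc"]].copy()
        table["enc"] = plot["enc"].values
        for axis in ("axis1", "axis2"):
            table[axis] = (
                pca.scores[axis].values
                if axis in pca.scores
                else float("nan")
            )
        result = correlation_matrix(table, method="t")
        result["rho_raw"] = [repr(v) for v in result["rho"]]
        result["pvalue_raw"] = [repr(v) for v in result["pvalue"]]
        _write(result, out / "correlations_table2.tsv")
        manifest["outputs"].append("correlations_table2.tsv")

    stage("correlations", do_correlations)

    _finish(out, manifest, log_lines)
    return manifest


def _finish(out: Path, manifest: dict, log_lines: list[str]) -> None:
    manifest["complete"] = all(
        name in manifest["outputs"] for name in CORE_OUTPUTS
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
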