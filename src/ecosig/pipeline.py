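"""End-to-end study orchestration with reproducibility metadata.

Two entry points mirror the two arms of the analysis:

* :func:`run_signature_study` — FASTA -> signature matrix -> nMDS ordination,
  ANOSIM and bootstrapped NJ consensus cladogram.
* :func:`run_ecoprofile_study` — hit table + manifest -> per-ORF and
  cumulative Hits/Mb matrices, affiliations, habitat statistics.

Every run echoes its configuration, master seed and per-output SHA-256
checksums into a ``run_manifest.json``; identical configurations produce
byte-identical data outputs.  One master seed is split deterministically
per randomized stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparative import (
    anosim,
    bootstrap_consensus,
    euclidean_distances,
    nmds,
)
from .ecogenomics import (
    PROFILES,
    cumulative_abundance,
    filter_hits,
    habitat_comparison,
    parse_hits,
    read_manifest,
    relative_abundance,
    top_hit_affiliation,
    affiliation_proportions,
)
from .signatures import read_fasta, signature_matrix, write_signature_tsv

logger = logging.getLogger("ecosig")

__all__ = ["RunConfig", "run_signature_study", "run_ecoprofile_study"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run; defaults match the study design
    (1000 nMDS starts, 500 bootstrap replicates, 999 permutations)."""

    outdir: str | Path = "ecosig_out"
    seed: int = 0
    fasta: str | Path | None = None
    groups: str | Path | None = None
    hits: str | Path | None = None
    manifest: str | Path | None = None
    orf_map: str | Path | None = None
    taxon_map: str | Path | None = None
    orf_list: str | Path | None = None
    n_starts: int = 1000
    n_boot: int = 500
    n_permutations: int = 999
    filter_profile: str = "METAGENOME"
    min_length: int = 4
    pearson_convention: str = "one_minus_r"
    dunn_method: str = "bonferroni"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    outdir: Path, config: RunConfig, timings: dict, outputs: dict, errors: dict
) -> None:
    manifest = {
        "ecosig_version": __version__,
        "config": config.as_dict(),
        "seed": config.seed,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {k: str(p) for k, p in outputs.items()},
        "checksums_sha256": {k: _sha256(Path(p)) for k, p in outputs.items()},
        "stage_errors": errors,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _read_two_column_tsv(path: str | Path, key: str, value: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if key in df.columns and value in df.columns:
        return dict(zip(df[key].astype(str), df[value].astype(str)))
    # headerless fallback: first column key, second value
    df = pd.read_csv(path, sep="\t", header=None)
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def run_signature_study(config: RunConfig) -> dict:
    """FASTA -> signatures -> ordination + ANOSIM + cladogram bundle.

    Stages that cannot run on the given input (e.g. an ordination of two
    sequences) are recorded as stage errors while earlier artifacts are
    still written.
    """
    if config.fasta is None:
        raise ValueError("config.fasta is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    errors: dict[str, str] = {}
    bundle: dict = {}

    t0 = time.perf_counter()
    records = read_fasta(config.fasta, min_length=config.min_length)
    sig = signature_matrix(records)
    sig_path = outdir / "signatures.tsv"
    write_signature_tsv(sig, sig_path)
    outputs["signatures"] = sig_path
    timings["signatures"] = time.perf_counter() - t0
    bundle["signatures"] = sig
    logger.info("signatures: %d sequences x %d cells", *sig.shape)

    groups = None
    if config.groups is not None:
        groups = _read_two_column_tsv(config.groups, "sequence_id", "group")

    t0 = time.perf_counter()
    try:
        dm = euclidean_distances(sig)
        ord_res = nmds(
            dm,
            n_starts=config.n_starts,
            seed=config.stage_seed("nmds"),
        )
        ord_path = outdir / "ordination.tsv"
        with ord_path.open("w") as fh:
            fh.write(f"# stress\t{ord_res.stress:.8f}\t"
                     f"n_starts\t{ord_res.n_starts_used}\t"
                     f"best_start\t{ord_res.best_start_seed}\n")
            ord_res.coordinates.to_csv(fh, sep="\t", float_format="%.6f")
        outputs["ordination"] = ord_path
        bundle["ordination"] = ord_res
    except (ValueError, KeyError) as e:
        errors["ordination"] = str(e)
        logger.error("ordination stage failed: %s", e)
    timings["ordination"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        if groups is None:
            raise ValueError("ANOSIM requires a groups table")
        dm = euclidean_distances(sig)
        an = anosim(
            dm,
            groups,
            n_permutations=config.n_permutations,
            seed=config.stage_seed("anosim"),
        )
        an_path = outdir / "anosim.tsv"
        with an_path.open("w") as fh:
            fh.write("R\tp_value\tn_permutations\tgroup_sizes\n")
            sizes = ";".join(f"{k}={v}" for k, v in sorted(an.group_sizes.items()))
            fh.write(f"{an.R:.6f}\t{an.p_value:.6f}\t{an.n_permutations}\t{sizes}\n")
        outputs["anosim"] = an_path
        bundle["anosim"] = an
    except (ValueError, KeyError) as e:
        errors["anosim"] = str(e)
        logger.error("anosim stage failed: %s", e)
    timings["anosim"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        clad = bootstrap_consensus(
            sig,
            n_boot=config.n_boot,
            seed=config.stage_seed("bootstrap"),
            convention=config.pearson_convention,
        )
        tree_path = outdir / "cladogram.nwk"
        clad.write(tree_path)
        outputs["cladogram"] = tree_path
        bundle["cladogram"] = clad
    except (ValueError, KeyError) as e:
        errors["cladogram"] = str(e)
        logger.error("cladogram stage failed: %s", e)
    timings["cladogram"] = time.perf_counter() - t0

    _write_manifest(outdir, config, timings, outputs, errors)
    bundle["outputs"] = outputs
    bundle["stage_errors"] = errors
    return bundle


def run_ecoprofile_study(config: RunConfig) -> dict:
    """Hit table + manifest + ORF map -> abundance and statistics bundle."""
    if config.hits is None or config.manifest is None:
        raise ValueError("config.hits and config.manifest are required")
    if config.filter_profile not in PROFILES:
        raise KeyError(
            f"unknown filter profile {config.filter_profile!r}; valid: "
            f"{sorted(PROFILES)}"
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    errors: dict[str, str] = {}
    bundle: dict = {}

    t0 = time.perf_counter()
    datasets = read_manifest(config.manifest)
    hits = parse_hits(config.hits)
    valid = filter_hits(hits, config.filter_profile)
    if not hits:
        warnings.warn("empty hit table: abundance matrices will be all zero")
    orf_map = None
    if config.orf_map is not None:
        orf_map = _read_two_column_tsv(config.orf_map, "orf_id", "phage")
    orf_ids = None
    if config.orf_list is not None:
        orf_ids = [
            line.strip()
            for line in Path(config.orf_list).read_text().splitlines()
            if line.strip()
        ]
    elif orf_map is not None:
        orf_ids = list(orf_map)

    am = relative_abundance(valid, datasets, orf_ids=orf_ids)
    am_path = outdir / "abundance_per_orf.tsv"
    am.to_csv(am_path, sep="\t", float_format="%.6f")
    outputs["abundance_per_orf"] = am_path
    bundle["abundance"] = am

    # heatmap-ready long format
    long_path = outdir / "abundance_long.tsv"
    am.reset_index().melt(
        id_vars="orf_id", var_name="dataset_id", value_name="hits_per_mb"
    ).to_csv(long_path, sep="\t", index=False, float_format="%.6f")
    outputs["abundance_long"] = long_path
    timings["abundance"] = time.perf_counter() - t0

    cum = None
    if orf_map is not None:
        t0 = time.perf_counter()
        try:
            cum = cumulative_abundance(am, orf_map)
            cum_path = outdir / "abundance_cumulative.tsv"
            cum.to_csv(cum_path, sep="\t", float_format="%.6f")
            outputs["abundance_cumulative"] = cum_path
            bundle["cumulative"] = cum
        except KeyError as e:
            errors["cumulative"] = str(e)
        timings["cumulative"] = time.perf_counter() - t0

    if config.taxon_map is not None:
        t0 = time.perf_counter()
        taxa = _read_two_column_tsv(config.taxon_map, "subject_id", "taxon")
        affil = top_hit_affiliation(
            hits, config.filter_profile, taxa, queries=orf_ids
        )
        aff_path = outdir / "affiliations.tsv"
        with aff_path.open("w") as fh:
            fh.write("query_id\ttaxon\n")
            for q, t in affil.items():
                fh.write(f"{q}\t{t}\n")
        outputs["affiliations"] = aff_path
        bundle["affiliations"] = affil
        try:
            props = affiliation_proportions(affil)
            prop_path = outdir / "affiliation_proportions.tsv"
            props.to_csv(prop_path, sep="\t", float_format="%.4f")
            outputs["affiliation_proportions"] = prop_path
            bundle["affiliation_proportions"] = props
        except ValueError as e:
            errors["affiliation_proportions"] = str(e)
        timings["affiliation"] = time.perf_counter() - t0

    if cum is not None:
        t0 = time.perf_counter()
        try:
            report = habitat_comparison(cum, datasets, dunn_method=config.dunn_method)
            rep_path = outdir / "habitat_tests.tsv"
            with rep_path.open("w") as fh:
                fh.write("phage\tH\tp_value\tgroup1\tgroup2\tz\tp_raw\tp_adj\n")
                for phage, rep in report.items():
                    for row in rep["dunn"].itertuples(index=False):
                        fh.write(
                            f"{phage}\t{rep['H']:.6f}\t{rep['p_value']:.6g}\t"
                            f"{row.group1}\t{row.group2}\t{row.z:.6f}\t"
                            f"{row.p_raw:.6g}\t{row.p_adj:.6g}\n"
                        )
            outputs["habitat_tests"] = rep_path
            bundle["habitat_report"] = report
        except (ValueError, KeyError) as e:
            errors["habitat_tests"] = str(e)
        timings["habitat_tests"] = time.perf_counter() - t0

    _write_manifest(outdir, config, timings, outputs, errors)
    bundle["outputs"] = outputs
    bundle["stage_errors"] = errors
    return bundle
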