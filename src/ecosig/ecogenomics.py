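"""Ecogenomic profiling of phage-encoded ORFs across metagenomic datasets.

Consumes precomputed tabular similarity-search results (BLAST outfmt-6
style), applies the study's hit-validity filters, and derives Hits/Mb
relative abundances, cumulative per-phage abundances, top-hit taxonomic
affiliations and habitat-level Kruskal-Wallis / Dunn statistics.  The
search engine itself is out of process, which keeps every step testable
without external databases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HitRecord",
    "FilterProfile",
    "DatasetInfo",
    "PROFILES",
    "HABITATS",
    "parse_hits",
    "filter_hits",
    "relative_abundance",
    "cumulative_abundance",
    "top_hit_affiliation",
    "affiliation_proportions",
    "habitat_comparison",
    "read_manifest",
    "write_manifest",
]

#: Habitat vocabulary used by the dataset manifests.
HABITATS = ("ENV", "HGUT", "HORAL", "HBODY", "HGV", "UTV")


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit of a phage ORF against a dataset sequence."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bit_score: float
    query_length: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must be in [0, 100]")
        if not self.dataset_id:
            object.__setattr__(self, "dataset_id", self.subject_id)

    @property
    def query_coverage(self) -> float:
        """Alignment-length based query coverage, percent."""
        return 100.0 * self.aln_length / self.query_length


@dataclass(frozen=True)
class FilterProfile:
    """Inclusive hit-validity thresholds (>= on identity/coverage/length,
    <= on e-value); unset constraints are not applied."""

    min_identity: float | None = None
    min_query_coverage: float | None = None
    min_aln_length: int | None = None
    max_evalue: float | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (
                self.min_identity,
                self.min_query_coverage,
                self.min_aln_length,
                self.max_evalue,
            )
        ):
            raise ValueError("filter profile with no constraints")

    def accepts(self, hit: HitRecord) -> bool:
        if self.min_identity is not None and hit.pct_identity < self.min_identity:
            return False
        if (
            self.min_query_coverage is not None
            and hit.query_coverage < self.min_query_coverage
        ):
            return False
        if self.min_aln_length is not None and hit.aln_length < self.min_aln_length:
            return False
        if self.max_evalue is not None and hit.evalue > self.max_evalue:
            return False
        return True


#: Named filter profiles used by the study's different search arms.
PROFILES: dict[str, FilterProfile] = {
    # metagenome Hits/Mb profiling
    "METAGENOME": FilterProfile(
        min_identity=35.0, min_query_coverage=50.0, max_evalue=1e-5
    ),
    # affiliation of ORFs to other phage genomes (top hit by bit score)
    "PHAGE_GENOME_AFFILIATION": FilterProfile(
        min_identity=35.0, min_aln_length=25, max_evalue=1e-5
    ),
    # affiliation of ORFs to candidate host genera
    "HOST_GENUS_AFFILIATION": FilterProfile(max_evalue=1e-3),
    # functional annotation searches
    "ANNOTATION": FilterProfile(min_identity=20.0, max_evalue=1e-5),
}


@dataclass(frozen=True)
class DatasetInfo:
    """One metagenomic dataset: id, habitat label and size in megabases."""

    dataset_id: str
    habitat: str
    size_mb: float

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ValueError(f"dataset {self.dataset_id!r}: size_mb must be > 0")
        if self.habitat not in HABITATS:
            raise ValueError(
                f"dataset {self.dataset_id!r}: habitat {self.habitat!r} not in "
                f"{HABITATS}"
            )


_COLS12 = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


def parse_hits(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    subject_to_dataset: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Parse a BLAST tabular hit file (12-column, or 13-column with qlen).

    For the 12-column dialect a ``query_lengths`` map is required.  Rows
    that fail numeric conversion are reported with their line numbers.
    ``subject_to_dataset`` optionally maps subject (contig) ids to dataset
    ids; by default the subject id is taken as the dataset id.
    """
    path = Path(path)
    records: list[HitRecord] = []
    bad_lines: list[int] = []
    missing_lengths: set[str] = set()
    ncols_seen = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                bad_lines.append(lineno)
                continue
            ncols_seen = len(parts)
            try:
                pct = float(parts[2])
                aln = int(parts[3])
                ev = float(parts[10])
                bit = float(parts[11])
                qlen = int(parts[12]) if len(parts) == 13 else None
            except ValueError:
                bad_lines.append(lineno)
                continue
            qid, sid = parts[0], parts[1]
            if qlen is None:
                if query_lengths is None or qid not in query_lengths:
                    missing_lengths.add(qid)
                    continue
                qlen = int(query_lengths[qid])
            ds = subject_to_dataset.get(sid, sid) if subject_to_dataset else sid
            try:
                records.append(
                    HitRecord(
                        query_id=qid,
                        subject_id=sid,
                        pct_identity=pct,
                        aln_length=aln,
                        evalue=ev,
                        bit_score=bit,
                        query_length=qlen,
                        dataset_id=ds,
                    )
                )
            except ValueError:
                bad_lines.append(lineno)
    if bad_lines:
        raise ValueError(f"malformed hit rows at lines: {bad_lines}")
    if missing_lengths:
        raise ValueError(
            "query length unavailable for queries: "
            f"{sorted(missing_lengths)} (12-column input needs a query_lengths map)"
        )
    return records


def filter_hits(
    hits: Iterable[HitRecord], profile: FilterProfile | str
) -> list[HitRecord]:
    """Retain hits meeting every threshold of the profile; order preserved."""
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise KeyError(
                f"unknown filter profile {profile!r}; valid profiles: "
                f"{sorted(PROFILES)}"
            ) from None
    return [h for h in hits if profile.accepts(h)]


def relative_abundance(
    filtered_hits: Iterable[HitRecord],
    datasets: Sequence[DatasetInfo],
    orf_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-ORF Hits/Mb matrix: valid hits divided by dataset size in Mb.

    Rows are ORF ids (``orf_ids`` fixes the row universe and order; by
    default the ORFs seen in the hits, sorted), columns are dataset ids in
    manifest order; unseen pairs are 0.
    """
    sizes = {d.dataset_id: d.size_mb for d in datasets}
    hits = list(filtered_hits)
    unknown = sorted({h.dataset_id for h in hits} - sizes.keys())
    if unknown:
        raise KeyError(f"hits reference datasets not in the manifest: {unknown}")
    if orf_ids is None:
        orf_ids = sorted({h.query_id for h in hits})
    ds_ids = [d.dataset_id for d in datasets]
    counts = pd.DataFrame(0.0, index=list(orf_ids), columns=ds_ids)
    for h in hits:
        if h.query_id not in counts.index:
            raise KeyError(f"hit query {h.query_id!r} not in orf_ids")
        counts.loc[h.query_id, h.dataset_id] += 1.0
    out = counts.div(pd.Series(sizes)[ds_ids], axis=1)
    out.index.name = "orf_id"
    return out


def cumulative_abundance(
    am: pd.DataFrame, orf_to_phage: Mapping[str, str]
) -> pd.DataFrame:
    """Per-phage cumulative Hits/Mb: exact sums of that phage's ORF rows."""
    unmapped = sorted(set(am.index) - set(orf_to_phage))
    if unmapped:
        raise KeyError(f"ORFs with no phage mapping: {unmapped}")
    phage = pd.Series({o: orf_to_phage[o] for o in am.index}, name="phage")
    out = am.groupby(phage).sum()
    out.index.name = "phage"
    return out


def top_hit_affiliation(
    hits: Iterable[HitRecord],
    profile: FilterProfile | str,
    subject_taxon: Mapping[str, str],
    queries: Sequence[str] | None = None,
) -> dict[str, str]:
    """Affiliate each query to the taxon of its best valid hit.

    Best = maximum bit score among hits passing the profile; ties broken by
    lower e-value, then lexicographic subject id.  Queries with no valid
    hit (or absent from the hit table but listed in ``queries``) map to
    "Unknown", as do subjects missing from the taxon map.
    """
    hits = list(hits)
    valid = filter_hits(hits, profile)
    best: dict[str, HitRecord] = {}
    for h in valid:
        cur = best.get(h.query_id)
        key = (-h.bit_score, h.evalue, h.subject_id)
        if cur is None or key < (-cur.bit_score, cur.evalue, cur.subject_id):
            best[h.query_id] = h
    universe = list(queries) if queries is not None else sorted(
        {h.query_id for h in hits} | best.keys()
    )
    out = {}
    for q in universe:
        h = best.get(q)
        out[q] = subject_taxon.get(h.subject_id, "Unknown") if h else "Unknown"
    return out


def affiliation_proportions(affiliations: Mapping[str, str]) -> pd.DataFrame:
    """Percentage of queries per taxon, over all queries and over assigned
    (non-Unknown) queries; each column sums to 100 within rounding."""
    if not affiliations:
        raise ValueError("no affiliations given")
    counts = pd.Series(list(affiliations.values())).value_counts()
    total = counts.sum()
    assigned = counts.drop(index="Unknown", errors="ignore")
    out = pd.DataFrame(
        {
            "pct_of_all": 100.0 * counts / total,
            "pct_of_assigned": (
                100.0 * assigned / assigned.sum()
                if assigned.sum() > 0
                else np.nan
            ),
        }
    )
    out.index.name = "taxon"
    if assigned.sum() == 0:
        warnings.warn("all queries Unknown; assigned-only proportions empty")
    return out


def _dunn_pairwise(
    groups: dict[str, np.ndarray], method: str
) -> pd.DataFrame:
    """Dunn's post hoc z-statistics on pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    i = 0
    for g in labels:
        m = groups[g].size
        mean_rank[g] = ranks[i : i + m].mean()
        i += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ga, gb = labels[a], labels[b]
            se = np.sqrt(base_var * (1 / groups[ga].size + 1 / groups[gb].size))
            z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append((ga, gb, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    df["p_adj"] = multipletests(df["p_raw"], method=method)[1]
    return df


def habitat_comparison(
    cum: pd.DataFrame,
    datasets: Sequence[DatasetInfo],
    dunn_method: str = "bonferroni",
) -> dict[str, dict]:
    """Per-phage Kruskal-Wallis test of cumulative abundances across habitats,
    with Dunn's pairwise post hoc comparisons.

    ``cum`` is a phage x dataset cumulative-abundance matrix.  Habitats with
    fewer than 2 datasets are excluded with a warning.  Each phage's report
    holds H, p, a Dunn table (z, raw and corrected p per habitat pair) and
    per-habitat mean +/- standard error.
    """
    if dunn_method not in ("bonferroni", "holm"):
        raise ValueError("dunn_method must be 'bonferroni' or 'holm'")
    by_hab: dict[str, list[str]] = {}
    for d in datasets:
        by_hab.setdefault(d.habitat, []).append(d.dataset_id)
    dropped = [h for h, ds in by_hab.items() if len(ds) < 2]
    for h in dropped:
        warnings.warn(f"habitat {h!r} has < 2 datasets; excluded")
        del by_hab[h]
    if len(by_hab) < 2:
        raise ValueError("need at least 2 habitats with >= 2 datasets each")

    report: dict[str, dict] = {}
    for phage in cum.index:
        groups = {
            h: cum.loc[phage, ds].to_numpy(dtype=float)
            for h, ds in by_hab.items()
        }
        samples = list(groups.values())
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            h_stat, p = 0.0, 1.0
        else:
            h_stat, p = stats.kruskal(*samples)
        summary = pd.DataFrame(
            {
                "mean": {h: g.mean() for h, g in groups.items()},
                "sem": {
                    h: g.std(ddof=1) / np.sqrt(g.size) for h, g in groups.items()
                },
                "n": {h: g.size for h, g in groups.items()},
            }
        )
        summary.index.name = "habitat"
        report[str(phage)] = {
            "H": float(h_stat),
            "p_value": float(p),
            "dunn": _dunn_pairwise(groups, dunn_method),
            "habitat_summary": summary,
        }
    return report


def read_manifest(path: str | Path) -> list[DatasetInfo]:
    """Read a dataset manifest TSV: dataset_id, habitat, size_mb."""
    df = pd.read_csv(path, sep="\t")
    required = {"dataset_id", "habitat", "size_mb"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return [
        DatasetInfo(str(r.dataset_id), str(r.habitat), float(r.size_mb))
        for r in df.itertuples()
    ]


def write_manifest(datasets: Sequence[DatasetInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "dataset_id": [d.dataset_id for d in datasets],
            "habitat": [d.habitat for d in datasets],
            "size_mb": [d.size_mb for d in datasets],
        }
    ).to_csv(path, sep="\t", index=False)
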