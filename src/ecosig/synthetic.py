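"""Synthetic data with the statistical structure the analyses assume.

The signature method rests on a co-evolution premise: a phage that has
replicated in one host lineage for a long time acquires the host
chromosome's oligonucleotide usage.  The generator makes that premise a
controllable ground truth: "host" genomes are drawn from distinct order-3
Markov models, "phage" genomes are drawn from their host's model, and an
optional migrant phage is drawn from one host's model while labelled as
infecting another — the scenario in which signature analysis should point
away from the labelled host.

Order 3 is the weakest compositional signal the tetranucleotide Z-score is
built to detect: the Z-score measures exactly the deviation of 4-mer counts
beyond what 2- and 3-mer composition predicts, so an order-3 chain plants a
signal in precisely that residual.

Hit-table simulation emits Poisson hit counts with known per-pair rates so
Hits/Mb matrices can be checked by hand, plus optional sub-threshold decoy
rows that a correct filter must remove exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .ecogenomics import DatasetInfo
from .signatures import _RC_PERM, SequenceRecord

__all__ = [
    "MarkovModel",
    "SyntheticPanel",
    "random_model",
    "perturb_model",
    "simulate_sequence",
    "simulate_panel",
    "simulate_hit_table",
    "implied_kmer_frequencies",
    "implied_signature_amplitude",
    "uniform_model",
    "write_panel",
    "write_hit_table",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MarkovModel:
    """Order-k Markov model over {A,C,G,T}.

    ``transition`` has shape (4**order, 4): row c is the distribution of
    the next base given the context with lexicographic code c.
    """

    order: int
    transition: np.ndarray
    model_id: str

    def __post_init__(self) -> None:
        expected = (4**self.order, 4)
        if self.transition.shape != expected:
            raise ValueError(f"transition must have shape {expected}")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("negative transition probabilities")


def random_model(
    seed: int, order: int = 3, concentration: float = 1.0, model_id: str = ""
) -> MarkovModel:
    """Random model with transition rows drawn from a symmetric Dirichlet.

    Lower ``concentration`` gives more skewed (more distinctive) rows; as
    concentration grows the model approaches the uniform i.i.d. chain.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    t = rng.dirichlet([concentration] * 4, size=4**order)
    t = t / t.sum(axis=1, keepdims=True)
    return MarkovModel(order=order, transition=t, model_id=model_id or f"model{seed}")


def perturb_model(m: MarkovModel, divergence: float, seed: int) -> MarkovModel:
    """Convex mixture (1-divergence)*m + divergence*random model."""
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    other = random_model(seed, order=m.order)
    t = (1.0 - divergence) * m.transition + divergence * other.transition
    return MarkovModel(
        order=m.order, transition=t, model_id=f"{m.model_id}_d{divergence:g}"
    )


@njit(cache=True)
def _simulate_chain(cumprobs, start_ctx, u, order):  # pragma: no cover - jit
    n = u.size
    out = np.empty(n + order, dtype=np.int8)
    ctx = start_ctx
    # write the initial context bases (most significant digit = oldest base)
    for i in range(order):
        shift = order - 1 - i
        out[i] = (ctx // 4**shift) % 4
    mask = 4 ** (order - 1)
    for i in range(n):
        row = cumprobs[ctx]
        x = u[i]
        b = 0
        while b < 3 and x > row[b]:
            b += 1
        out[order + i] = b
        ctx = (ctx % mask) * 4 + b
    return out


def simulate_sequence(
    m: MarkovModel, length: int, seed: int, record_id: str = "", role: str = "other"
) -> SequenceRecord:
    """Simulate a sequence of exactly ``length`` bases from the model.

    The initial context is drawn uniformly over the 4**order contexts;
    subsequent bases follow the transition rows.  Deterministic given seed.
    """
    if length <= m.order:
        raise ValueError("length must exceed the model order")
    rng = np.random.default_rng(seed)
    start_ctx = int(rng.integers(0, 4**m.order))
    u = rng.random(length - m.order)
    cum = np.cumsum(m.transition, axis=1)
    codes = _simulate_chain(cum, start_ctx, u, m.order)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return SequenceRecord(
        id=record_id or f"{m.model_id}_sim{seed}", sequence=seq, role=role
    )


def _context_stationary(m: MarkovModel) -> np.ndarray:
    """Stationary distribution of the context chain (power iteration)."""
    k = m.order
    nctx = 4**k
    mask = 4 ** (k - 1)
    # transition on contexts: ctx -> (ctx % mask)*4 + b with prob t[ctx, b]
    p = np.zeros((nctx, nctx))
    ctx = np.arange(nctx)
    nxt_idx = (ctx % mask)[:, None] * 4 + np.arange(4)[None, :]
    p[ctx[:, None], nxt_idx] = m.transition
    pi = np.full(nctx, 1.0 / nctx)
    for _ in range(2000):
        nxt = pi @ p
        if np.abs(nxt - pi).max() < 1e-13:
            return nxt
        pi = nxt
    return pi


def implied_kmer_frequencies(m: MarkovModel, k: int = 4) -> np.ndarray:
    """Model-implied stationary k-mer frequencies (k = order + 1 or order)."""
    pi = _context_stationary(m)
    if k == m.order:
        return pi
    if k != m.order + 1:
        raise ValueError("only k = order or order + 1 supported")
    freq = (pi[:, None] * m.transition).ravel()
    return freq / freq.sum()


def uniform_model(order: int = 3, model_id: str = "uniform") -> MarkovModel:
    """The i.i.d. uniform chain: every transition row is (1/4, ..., 1/4)."""
    t = np.full((4**order, 4), 0.25)
    return MarkovModel(order=order, transition=t, model_id=model_id)


def implied_signature_amplitude(m: MarkovModel) -> float:
    """Model-implied tetranucleotide Z-signal amplitude per sqrt(base).

    The Z-score of word w on an L-base sequence converges to
    sqrt(L) * s_w, where s_w is the standardized deviation of the model's
    stationary 4-mer frequency from its maximal-order (2-/3-mer based)
    expectation.  This returns ||s||_2 over the 256 cells, computed on the
    reverse-complement-symmetrized frequencies the signature uses, so that
    two models with equal amplitude yield (asymptotically) equal-norm
    signatures at equal sequence length.
    """
    if m.order != 3:
        raise ValueError("amplitude is defined for order-3 models")
    f4 = implied_kmer_frequencies(m, 4)
    f3 = implied_kmer_frequencies(m, 3)
    f2 = f3.reshape(16, 4).sum(axis=1)
    g4 = (f4 + f4[_RC_PERM[4]]) / 2.0
    g3 = (f3 + f3[_RC_PERM[3]]) / 2.0
    g2 = (f2 + f2[_RC_PERM[2]]) / 2.0
    w = np.arange(256)
    pre = w >> 2
    suf = w & 0x3F
    mid = pre & 0xF
    with np.errstate(divide="ignore", invalid="ignore"):
        e = g3[pre] * g3[suf] / g2[mid]
        var = e * (1.0 - g3[pre] / g2[mid]) * (1.0 - g3[suf] / g2[mid])
    s = np.zeros(256)
    ok = np.isfinite(var) & (var > 0) & np.isfinite(e) & (e > 0)
    s[ok] = (g4[ok] - e[ok]) / np.sqrt(var[ok])
    return float(np.linalg.norm(s))


def _amplitude_calibrated_model(
    rand: MarkovModel, target_amplitude: float, model_id: str
) -> MarkovModel:
    """Mix ``rand`` with the uniform chain to hit a target implied amplitude.

    Amplitude grows monotonically from 0 (pure uniform) to the amplitude of
    ``rand`` as the mixing weight goes 0 -> 1, so a bisection on the weight
    is well-posed.  If the target exceeds what ``rand`` can provide, the
    pure ``rand`` model is returned.
    """
    uni = uniform_model(rand.order).transition

    def mix(alpha: float) -> np.ndarray:
        t = (1.0 - alpha) * uni + alpha * rand.transition
        return t / t.sum(axis=1, keepdims=True)

    def amp(alpha: float) -> float:
        return implied_signature_amplitude(
            MarkovModel(order=rand.order, transition=mix(alpha), model_id="_")
        )

    if amp(1.0) <= target_amplitude:
        alpha = 1.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(40):
            midpt = 0.5 * (lo + hi)
            if amp(midpt) < target_amplitude:
                lo = midpt
            else:
                hi = midpt
        alpha = 0.5 * (lo + hi)
    return MarkovModel(order=rand.order, transition=mix(alpha), model_id=model_id)


@dataclass
class SyntheticPanel:
    """Host + phage sequences with ground-truth generating models."""

    records: list[SequenceRecord]
    truth: dict[str, str]
    params: dict
    migrant_id: str | None = None
    migrant_labeled_host: str | None = None

    def __post_init__(self) -> None:
        missing = [r.id for r in self.records if r.id not in self.truth]
        if missing:
            raise ValueError(f"truth map misses records: {missing}")


def simulate_panel(
    n_hosts: int = 4,
    phages_per_host: int = 3,
    host_length: int = 2_000_000,
    phage_length: int = 40_000,
    divergence_between_hosts: float = 0.6,
    seed: int = 0,
    include_migrant: bool = True,
    concentration: float = 1.0,
) -> SyntheticPanel:
    """Simulate a host/phage panel with known host-of-origin labels.

    Each host genome comes from its own order-3 model, built by mixing an
    independent random model with the uniform chain.  The mixing weight is
    calibrated per host so that every host carries the same model-implied
    signature amplitude, equal to ``divergence_between_hosts`` times the
    smallest amplitude among the raw random draws: divergence 0 makes all
    hosts identical (uniform), and larger divergence makes their
    compositions stronger and therefore farther apart.  Equalizing the
    amplitude matters because signature norms grow with both amplitude and
    genome length; without it, host-model draws with accidentally weak
    composition would attract every phage in a Euclidean comparison for
    reasons unrelated to host-of-origin signal.

    Phages are simulated from their host's model — the co-evolved state the
    signature method assumes.  When ``include_migrant`` is set, one extra
    phage is generated from host 0's model but labelled as infecting host 1
    (a recent host switch whose signature should still point to host 0).
    """
    if n_hosts < 2:
        raise ValueError("need at least 2 hosts")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(2 * n_hosts + 2)]
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    rands = [
        random_model(child_seeds[1 + h], concentration=concentration)
        for h in range(n_hosts)
    ]
    target = divergence_between_hosts * min(
        implied_signature_amplitude(r) for r in rands
    )
    models = []
    for h in range(n_hosts):
        mh = _amplitude_calibrated_model(rands[h], target, f"host{h}")
        models.append(mh)
        rec = simulate_sequence(
            mh, host_length, child_seeds[1 + n_hosts + h], f"host{h}", role="bacterium"
        )
        records.append(rec)
        truth[rec.id] = mh.model_id

    phage_rng = np.random.default_rng(child_seeds[-2])
    for h in range(n_hosts):
        for p in range(phages_per_host):
            s = int(phage_rng.integers(0, 2**31 - 1))
            rec = simulate_sequence(
                models[h], phage_length, s, f"phage_{h}_{p}", role="phage"
            )
            records.append(rec)
            truth[rec.id] = models[h].model_id

    migrant_id = labeled = None
    if include_migrant:
        rec = simulate_sequence(
            models[0], phage_length, child_seeds[-1], "migrant_phage", role="phage"
        )
        records.append(rec)
        truth[rec.id] = models[0].model_id
        migrant_id, labeled = rec.id, models[1].model_id

    params = dict(
        n_hosts=n_hosts,
        phages_per_host=phages_per_host,
        host_length=host_length,
        phage_length=phage_length,
        model_divergence=divergence_between_hosts,
        seed=seed,
        include_migrant=include_migrant,
        concentration=concentration,
    )
    return SyntheticPanel(
        records=records,
        truth=truth,
        params=params,
        migrant_id=migrant_id,
        migrant_labeled_host=labeled,
    )


def simulate_hit_table(
    orfs: Sequence[str],
    datasets: Sequence[DatasetInfo],
    rate_matrix: np.ndarray,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    query_length: int = 200,
):
    """Simulate a 13-column tabular hit file with known true hit counts.

    Hit counts per (ORF, dataset) pair are Poisson with the given rates;
    every true hit is drawn to pass the METAGENOME validity profile.  A
    ``decoy_fraction`` of all emitted rows (in expectation) are decoys that
    fail at least one threshold.  Returns ``(rows, true_counts, decoy_flags)``
    where rows are 13-column tab-separated strings, ``true_counts`` is the
    ORF x dataset matrix of non-decoy hits, and ``decoy_flags`` marks decoy
    rows by index.
    """
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    if rate_matrix.shape != (len(orfs), len(datasets)):
        raise ValueError("rate_matrix shape must be (n_orfs, n_datasets)")
    if np.any(rate_matrix < 0):
        raise ValueError("rates must be >= 0")
    if not 0 <= decoy_fraction < 1:
        raise ValueError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_counts = rng.poisson(rate_matrix)
    rows: list[str] = []
    decoy_flags: list[bool] = []

    def _true_row(orf: str, ds: str) -> str:
        pct = rng.uniform(35.0, 100.0)
        aln = int(rng.integers(query_length // 2, query_length + 1))  # cov >= 50%
        ev = 10.0 ** (-rng.uniform(6.0, 30.0))
        bit = rng.uniform(50.0, 500.0)
        return _format_row(orf, ds, pct, aln, ev, bit, query_length)

    def _decoy_row(orf: str, ds: str) -> str:
        mode = rng.integers(0, 3)
        pct = rng.uniform(35.0, 100.0)
        aln = int(rng.integers(query_length // 2, query_length + 1))
        ev = 10.0 ** (-rng.uniform(6.0, 30.0))
        if mode == 0:
            pct = rng.uniform(0.0, 34.9)
        elif mode == 1:
            aln = int(rng.integers(1, query_length // 2))  # cov < 50%
        else:
            ev = 10.0 ** (-rng.uniform(0.0, 4.9))
        bit = rng.uniform(20.0, 60.0)
        return _format_row(orf, ds, pct, aln, ev, bit, query_length)

    def _format_row(orf, ds, pct, aln, ev, bit, qlen) -> str:
        mism = max(0, int(round(aln * (1 - pct / 100.0))))
        return "\t".join(
            [
                orf,
                ds,
                f"{pct:.2f}",
                str(aln),
                str(mism),
                "0",
                "1",
                str(aln),
                "1",
                str(aln),
                f"{ev:.3e}",
                f"{bit:.1f}",
                str(qlen),
            ]
        )

    n_true_total = int(true_counts.sum())
    for i, orf in enumerate(orfs):
        for j, d in enumerate(datasets):
            for _ in range(int(true_counts[i, j])):
                rows.append(_true_row(orf, d.dataset_id))
                decoy_flags.append(False)
    if decoy_fraction > 0:
        n_decoys = int(
            rng.poisson(n_true_total * decoy_fraction / (1 - decoy_fraction))
        ) if n_true_total else int(rng.poisson(1 + 10 * decoy_fraction))
        for _ in range(n_decoys):
            i = int(rng.integers(0, len(orfs)))
            j = int(rng.integers(0, len(datasets)))
            rows.append(_decoy_row(orfs[i], datasets[j].dataset_id))
            decoy_flags.append(True)
    return rows, true_counts, np.array(decoy_flags, dtype=bool)


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> dict[str, Path]:
    """Write a panel as FASTA + truth TSV + params JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "panel.fasta"
    with fasta.open("w") as fh:
        for rec in panel.records:
            fh.write(f">{rec.id} role={rec.role}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    truth = outdir / "truth.tsv"
    with truth.open("w") as fh:
        fh.write("record_id\tmodel_id\n")
        for rec in panel.records:
            fh.write(f"{rec.id}\t{panel.truth[rec.id]}\n")
    params = outdir / "params.json"
    meta = dict(panel.params)
    meta["migrant_id"] = panel.migrant_id
    meta["migrant_labeled_host"] = panel.migrant_labeled_host
    params.write_text(json.dumps(meta, indent=2) + "\n")
    return {"fasta": fasta, "truth": truth, "params": params}


def write_hit_table(rows: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
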