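"""Mock-community metabarcoding simulator.

Generates datasets with the statistical structure of an indexed-PCR /
replicate-run experiment: an equimolar pool of target taxa distorted by
lognormal amplification bias, a Zipf-decaying long tail of rare non-target
taxa, one fixed amplicon library per indexed primer (pool proportions times
index-specific lognormal factors), and sequencing runs that independently
multinomially resample each fixed library.  Because the per-primer library
proportions are shared across runs, within-primer between-run variation is
pure random sampling — the mechanism whose consequences the analysis modules
quantify.

Defaults are the study conditions: 34 equimolar targets whose realized read
counts span about three orders of magnitude, 86 rare taxa totalling 0.3% of
reads, 7 indexed primers, 2 runs, and per-sample depths drawn uniformly from
the observed range 45,609-78,387 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .table import OTUTable

__all__ = [
    "MockModel",
    "GroundTruth",
    "DEFAULT_INDEX_MAP",
    "PRIMER_FWD",
    "PRIMER_REV",
    "simulate_pool",
    "simulate_libraries",
    "simulate_runs",
    "simulate_table",
    "simulate_fastq",
    "make_templates",
]

# 6-base sample indices and the degenerate COI primer pair used with them
DEFAULT_INDEX_MAP = {
    "P1": "AGACGC",
    "P2": "AGTGTA",
    "P3": "ACTAGC",
    "P4": "ACAGTC",
    "P5": "ATCGAC",
    "P6": "ATGTCG",
    "P7": "ATAGCA",
}
PRIMER_FWD = "GGWACWGGWTGAACWGTWTAYCCYCC"
PRIMER_REV = "TAIACYTCIGGRTGICCRAARAAYCA"

#: stop codons of the invertebrate mitochondrial code (translation table 5)
_STOPS = ("TAA", "TAG")


@dataclass(frozen=True)
class MockModel:
    """Generative parameters of the simulator.

    target_bias_sigma and primer_bias_sigma are natural-log-scale standard
    deviations of the lognormal amplification and index-specific bias
    factors.  depth_range is the closed interval reads-per-sample are drawn
    from; set both ends equal for a fixed-depth analytic mode.
    """

    n_target: int = 34
    n_rare: int = 86
    n_primers: int = 7
    n_runs: int = 2
    target_bias_sigma: float = 1.5
    rare_total_fraction: float = 0.003
    rare_tail_shape: float = 2.5
    primer_bias_sigma: float = 0.15
    depth_range: tuple[int, int] = (45_609, 78_387)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_total_fraction < 1.0:
            raise ValueError("rare_total_fraction must be in [0, 1)")
        if self.target_bias_sigma < 0 or self.primer_bias_sigma < 0:
            raise ValueError("bias sigmas must be >= 0")
        for name in ("n_target", "n_primers", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_rare < 0:
            raise ValueError("n_rare must be >= 0")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= low <= high")

    @property
    def n_taxa(self) -> int:
        return self.n_target + self.n_rare

    def taxon_ids(self) -> list[str]:
        return [f"OTU{i + 1:03d}" for i in range(self.n_taxa)]


@dataclass(frozen=True)
class GroundTruth:
    """The simulator's latent state: pool and per-primer library proportions."""

    taxon_ids: tuple[str, ...]
    pool: np.ndarray                   # a_i, sums to 1
    is_target: np.ndarray              # bool per taxon
    libraries: pd.DataFrame | None = None  # taxa x primers, columns sum to 1
    depths: pd.DataFrame | None = None     # primers x runs read depths

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"pool": self.pool, "is_target": self.is_target},
                          index=list(self.taxon_ids))
        if self.libraries is not None:
            df = df.join(self.libraries.add_prefix("theta_"))
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")


def _seed_streams(model: MockModel, seed=None) -> np.random.SeedSequence:
    if seed is None:
        seed = model.seed
    return np.random.SeedSequence(seed)


def simulate_pool(model: MockModel, seed=None) -> GroundTruth:
    """Draw the post-amplification pool proportions a_i.

    Target taxa start equimolar, are multiplied by lognormal(0,
    target_bias_sigma) amplification factors and renormalized to
    (1 - rare_total_fraction); rare taxa share rare_total_fraction with
    Zipf-decaying proportions k^-rare_tail_shape.
    """
    rng = np.random.default_rng(_seed_streams(model, seed).spawn(3)[0])
    target = np.full(model.n_target, 1.0 / model.n_target)
    if model.target_bias_sigma > 0:
        target = target * rng.lognormal(0.0, model.target_bias_sigma, model.n_target)
    target = target / target.sum() * (1.0 - model.rare_total_fraction)

    if model.n_rare > 0:
        ranks = np.arange(1, model.n_rare + 1, dtype=float)
        rare = ranks ** -model.rare_tail_shape
        rare = rare / rare.sum() * model.rare_total_fraction
    else:
        rare = np.empty(0)
    pool = np.concatenate([target, rare])
    is_target = np.concatenate(
        [np.ones(model.n_target, bool), np.zeros(model.n_rare, bool)]
    )
    return GroundTruth(tuple(model.taxon_ids()), pool, is_target)


def simulate_libraries(truth: GroundTruth, model: MockModel, seed=None) -> GroundTruth:
    """Distort the pool into one fixed library per indexed primer.

    theta_{i,p} is proportional to a_i times an index-specific lognormal(0,
    primer_bias_sigma) factor, renormalized per primer; with sigma 0 every
    primer's library equals the pool.
    """
    rng = np.random.default_rng(_seed_streams(model, seed).spawn(3)[1])
    primers = [f"P{p + 1}" for p in range(model.n_primers)]
    thetas = {}
    for p in primers:
        eps = (
            rng.lognormal(0.0, model.primer_bias_sigma, len(truth.pool))
            if model.primer_bias_sigma > 0
            else np.ones(len(truth.pool))
        )
        theta = truth.pool * eps
        thetas[p] = theta / theta.sum()
    libraries = pd.DataFrame(thetas, index=list(truth.taxon_ids))
    return replace(truth, libraries=libraries)


def simulate_runs(truth: GroundTruth, model: MockModel, seed=None) -> OTUTable:
    """Multinomially resample each primer's fixed library in every run.

    Sample (p, r) draws multinomial(N_{p,r}, theta_{.,p}); the SAME theta is
    used in both runs, so within-primer between-run variation is pure
    resampling.  Returns an annotated samples-x-OTUs table with sample ids
    ``P{p}R{r}``.
    """
    if truth.libraries is None:
        raise ValueError("call simulate_libraries before simulate_runs")
    ss = _seed_streams(model, seed).spawn(3)[2]
    rng = np.random.default_rng(ss)
    lo, hi = model.depth_range
    rows, meta = {}, {}
    for r in range(1, model.n_runs + 1):
        for p_i, primer in enumerate(truth.libraries.columns, start=1):
            depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, truth.libraries[primer].to_numpy())
            sid = f"{primer}R{r}"
            rows[sid] = counts
            meta[sid] = {"primer_index": p_i, "run": r}
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(truth.taxon_ids))
    sample_meta = pd.DataFrame.from_dict(meta, orient="index")
    otu_meta = pd.DataFrame(
        {"is_target": truth.is_target, "label": list(truth.taxon_ids)},
        index=list(truth.taxon_ids),
    )
    return OTUTable(counts, sample_meta, otu_meta, allow_empty_samples=True)


def simulate_table(model: MockModel, seed=None) -> tuple[OTUTable, GroundTruth]:
    """Pool -> libraries -> runs in one call; returns (table, ground truth)."""
    truth = simulate_pool(model, seed)
    truth = simulate_libraries(truth, model, seed)
    table = simulate_runs(truth, model, seed)
    depths = (
        table.sample_totals()
        .rename("depth")
        .to_frame()
        .join(table.sample_meta)
        .pivot_table(index="primer_index", columns="run", values="depth")
    )
    truth = replace(truth, depths=depths)
    return table, truth


# ---------------------------------------------------------------------------
# FASTQ-level simulation
# ---------------------------------------------------------------------------

def make_templates(model: MockModel, length: int = 313, min_dist: int = 20,
                   seed=None) -> list[str]:
    """Random in-frame COI-like template per taxon.

    Sequences are built codon-wise avoiding TAA/TAG (no frame-0 stops under
    translation table 5), then padded to ``length``; templates are kept at
    Hamming distance >= ``min_dist`` from each other so sequencing-error
    variants cannot precluster across taxa.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        model.seed if seed is None else seed).spawn(4)[3])
    bases = np.array(list("ACGT"))
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    n_codons = length // 3
    pad = length - 3 * n_codons
    templates: list[str] = []
    attempts = 0
    while len(templates) < model.n_taxa:
        attempts += 1
        if attempts > 200 * model.n_taxa:
            raise RuntimeError("could not place mutually distant templates")
        seq = "".join(rng.choice(codons, n_codons))
        if pad:
            seq += "".join(rng.choice(bases, pad))
        if all(_hamming(seq, t) >= min_dist for t in templates):
            templates.append(seq)
    return templates


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _resolve_iupac(primer: str, rng) -> str:
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "I": "ACGT",
    }
    return "".join(rng.choice(list(table[b])) for b in primer)


def simulate_fastq(
    truth: GroundTruth,
    model: MockModel,
    fwd_path,
    rev_path,
    index_map: dict[str, str] | None = None,
    primer_fwd: str = PRIMER_FWD,
    primer_rev: str = PRIMER_REV,
    error_rate: float = 0.0,
    read_length: int = 250,
    base_quality: int = 38,
    templates: list[str] | None = None,
    run: int = 1,
    index_conflict_fraction: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Emit paired FASTQ for one sequencing run of the simulated libraries.

    Each amplicon is index + concrete primer + taxon template + reverse
    complement of (index + primer); the mates are its first/last
    ``read_length`` bases with independent per-base substitution errors at
    ``error_rate`` and constant Phred ``base_quality``.  Degenerate primer
    positions are resolved once per amplicon.  A fraction of reads can be
    given deliberately mismatched forward/reverse indices to exercise the
    tag-jump guard.  Returns the per-sample, per-taxon read counts actually
    written (the FASTQ-level ground truth).
    """
    if truth.libraries is None:
        raise ValueError("call simulate_libraries before simulate_fastq")
    if index_map is None:
        index_map = {p: DEFAULT_INDEX_MAP[p] for p in truth.libraries.columns}
    ss = np.random.SeedSequence(model.seed if seed is None else seed).spawn(5)[4]
    rng = np.random.default_rng(ss)
    if templates is None:
        templates = make_templates(model, seed=seed)
    bases = "ACGT"

    lo, hi = model.depth_range
    written: dict[str, np.ndarray] = {}
    fh_f, fh_r = open(fwd_path, "w"), open(rev_path, "w")
    try:
        read_no = 0
        for primer in truth.libraries.columns:
            depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, truth.libraries[primer].to_numpy())
            written[f"{primer}R{run}"] = counts
            for t_i, n_reads in enumerate(counts):
                for _ in range(n_reads):
                    read_no += 1
                    idx_f = idx_r = index_map[primer]
                    if index_conflict_fraction > 0 and rng.random() < index_conflict_fraction:
                        others = [v for k, v in index_map.items() if k != primer]
                        idx_r = others[rng.integers(len(others))]
                    amplicon = (
                        idx_f
                        + _resolve_iupac(primer_fwd, rng)
                        + templates[t_i]
                        + _revcomp(_resolve_iupac(primer_rev, rng))
                        + _revcomp(idx_r)
                    )
                    r1 = amplicon[:read_length]
                    r2 = _revcomp(amplicon)[:read_length]
                    if error_rate > 0:
                        r1 = _mutate(r1, error_rate, rng, bases)
                        r2 = _mutate(r2, error_rate, rng, bases)
                    qual = chr(base_quality + 33) * read_length
                    rid = f"sim_{primer}_r{run}_{read_no}"
                    fh_f.write(f"@{rid}\n{r1}\n+\n{qual[:len(r1)]}\n")
                    fh_r.write(f"@{rid}\n{r2}\n+\n{qual[:len(r2)]}\n")
    finally:
        fh_f.close()
        fh_r.close()
    return pd.DataFrame.from_dict(written, orient="index",
                                  columns=list(truth.taxon_ids))


def _mutate(seq: str, rate: float, rng, bases: str) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4] \
            if out[i] in bases else out[i]
    return "".join(out)
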