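"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed):
re-running with the same arguments reproduces the output bit for bit.
The returned truth objects carry everything needed to score downstream
recovery (planted effects, masks, planted module members, LAD intervals,
voxel overlap) without re-deriving it.

Generators emulate, at desk scale:

* label-free proteomics intensity matrices with group effects and
  intensity-dependent (missing-not-at-random) censoring;
* degree-heterogeneous protein-interaction graphs with a planted,
  densified module;
* beta-uniform mixture p-value samples;
* a chromosome with GATC motifs, planted lamina-associated intervals and
  Poisson-like read sampling for DamID;
* paired 3D voxel images with an exactly controlled foreground overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "LfqTruth",
    "NetworkTruth",
    "DamidTruth",
    "DamidDataset",
    "gen_lfq_matrix",
    "gen_ppi_network",
    "gen_bum_pvalues",
    "gen_damid_dataset",
    "gen_voxel_pair",
    "gen_mwcs_suite",
    "write_fasta",
    "write_bed_starts",
]


# ---------------------------------------------------------------------------
# shared containers

@dataclass
class AbundanceMatrix:
    """Proteins x samples log2 intensities; NaN marks a missing cell."""

    values: pd.DataFrame  # index: protein ids, columns: sample ids
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate protein or sample identifiers")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), dict(self.groups))


@dataclass
class LfqTruth:
    """Ground truth of a simulated label-free quantification experiment."""

    differential_ids: set[str]
    true_log2fc: pd.Series  # per protein, log2 units; 0 for non-differential
    mnar_mask: pd.DataFrame  # True where censored by low intensity
    mcar_mask: pd.DataFrame  # True where missing completely at random
    latent: pd.DataFrame  # noise-free-missingness intensities before masking


@dataclass
class NetworkTruth:
    planted_members: set[str]
    planted_score_boost: float = 0.0


@dataclass
class DamidTruth:
    """Planted lamina-associated intervals, half-open 0-based."""

    lad_intervals: list[tuple[str, int, int]]
    enrichment: float = 1.0

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.lad_intervals:
            if chrom not in chrom_lengths:
                raise ValueError(f"LAD on unknown chromosome {chrom}")
            if not (0 <= start < end <= chrom_lengths[chrom]):
                raise ValueError(f"LAD ({chrom}, {start}, {end}) outside chromosome")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ordered = sorted(ivs)
            if ivs != ordered:
                raise ValueError("LAD intervals must be sorted")
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise ValueError("LAD intervals must not overlap")


@dataclass
class DamidDataset:
    chrom: str
    sequence: str
    fusion_starts: np.ndarray  # 0-based read start positions, Dam-laminB1
    control_starts: np.ndarray  # untethered Dam
    truth: DamidTruth = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# proteomics

def gen_lfq_matrix(
    n_proteins: int = 2000,
    n_per_group: int = 3,
    frac_diff: float = 0.1,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.3,
    mnar_quantile: float = 0.25,
    seed: int = 0,
    p_mnar: float = 0.8,
    p_mcar: float = 0.02,
) -> tuple[AbundanceMatrix, LfqTruth]:
    """Simulate a two-group label-free intensity matrix with MNAR censoring.

    Baseline log2 intensities are normal per protein (log-normal on the
    linear scale); ``round(frac_diff * n_proteins)`` proteins receive a
    +/- ``effect_log2fc`` shift in group B. Cells whose latent intensity
    falls below the ``mnar_quantile`` quantile of their sample column are
    censored with probability ``p_mnar``; surviving cells are additionally
    dropped completely at random with probability ``p_mcar``.
    """
    if n_proteins <= 0 or n_per_group < 2:
        raise ValueError("need n_proteins > 0 and n_per_group >= 2")
    if not 0 <= frac_diff <= 1:
        raise ValueError("frac_diff must lie in [0, 1]")
    if not 0 <= mnar_quantile < 1:
        raise ValueError("mnar_quantile must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    samples = [f"A{r+1}" for r in range(n_per_group)] + [f"B{r+1}" for r in range(n_per_group)]
    groups = {s: s[0] for s in samples}

    base = rng.normal(25.0, 2.0, size=n_proteins)
    n_diff = round(frac_diff * n_proteins)
    diff_idx = rng.choice(n_proteins, size=n_diff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    true_fc = np.zeros(n_proteins)
    true_fc[diff_idx] = signs * effect_log2fc

    latent = np.empty((n_proteins, 2 * n_per_group))
    for j, s in enumerate(samples):
        shift = true_fc if groups[s] == "B" else 0.0
        latent[:, j] = base + shift + rng.normal(0.0, noise_sd, size=n_proteins)

    mnar = np.zeros_like(latent, dtype=bool)
    for j in range(latent.shape[1]):
        thr = np.quantile(latent[:, j], mnar_quantile)
        low = latent[:, j] < thr
        mnar[:, j] = low & (rng.random(n_proteins) < p_mnar)
    mcar = (~mnar) & (rng.random(latent.shape) < p_mcar)

    values = latent.copy()
    values[mnar | mcar] = np.nan
    df = pd.DataFrame(values, index=ids, columns=samples)
    latent_df = pd.DataFrame(latent, index=ids, columns=samples)
    truth = LfqTruth(
        differential_ids={ids[i] for i in diff_idx},
        true_log2fc=pd.Series(true_fc, index=ids),
        mnar_mask=pd.DataFrame(mnar, index=ids, columns=samples),
        mcar_mask=pd.DataFrame(mcar, index=ids, columns=samples),
        latent=latent_df,
    )
    return AbundanceMatrix(df, groups), truth


# ---------------------------------------------------------------------------
# interaction network

def gen_ppi_network(
    n_nodes: int = 200,
    mean_degree: float = 4.0,
    module_size: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], NetworkTruth]:
    """Preferential-attachment graph with a densified planted module.

    The background is a Barabasi-Albert graph (degree-heterogeneous,
    connected). A connected subset of ``module_size`` nodes grown by
    breadth-first search from a random node is densified with random
    internal edges until its edge density is at least twice the
    background density. Node ids are ``N0000``-style strings.
    """
    import networkx as nx

    if module_size > n_nodes:
        raise ValueError("module_size exceeds n_nodes")
    if mean_degree < 1:
        raise ValueError("mean_degree must be >= 1")

    rng = np.random.default_rng(seed)
    m = max(1, round(mean_degree / 2))
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))

    start = int(rng.integers(n_nodes))
    members: list[int] = [start]
    frontier = list(g.neighbors(start))
    while len(members) < module_size:
        if not frontier:  # should not happen on a connected graph
            rest = [v for v in g.nodes if v not in members]
            frontier = [rest[int(rng.integers(len(rest)))]]
        nxt = frontier.pop(int(rng.integers(len(frontier))))
        if nxt in members:
            continue
        members.append(nxt)
        frontier.extend(v for v in g.neighbors(nxt) if v not in members)

    background_density = 2 * g.number_of_edges() / (n_nodes * (n_nodes - 1))
    target = 2 * background_density
    k = len(members)
    if k >= 2:
        possible = [
            (u, v) for i, u in enumerate(members) for v in members[i + 1 :]
        ]
        rng.shuffle(possible)
        for u, v in possible:
            internal = g.subgraph(members).number_of_edges()
            if internal / (k * (k - 1) / 2) >= target:
                break
            if not g.has_edge(u, v):
                g.add_edge(u, v)

    name = {v: f"N{v:04d}" for v in g.nodes}
    edges = sorted((min(name[u], name[v]), max(name[u], name[v])) for u, v in g.edges)
    truth = NetworkTruth(planted_members={name[v] for v in members})
    return edges, truth


def gen_mwcs_suite(
    n_instances: int = 100,
    max_nodes: int = 12,
    seed: int = 12345,
) -> list[tuple[list[tuple[str, str]], dict[str, float]]]:
    """Fixture suite of small connected scored graphs for solver benchmarking.

    Each instance is a connected Erdos-Renyi-style graph on 6..max_nodes
    nodes with N(0, 2) node scores (roughly half positive). Returns
    (edge list, score map) pairs; fully deterministic in ``seed``.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    suite = []
    while len(suite) < n_instances:
        n = int(rng.integers(6, max_nodes + 1))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        scores = {f"n{v}": float(rng.normal(0.0, 2.0)) for v in g.nodes}
        edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
        suite.append((edges, scores))
    return suite


# ---------------------------------------------------------------------------
# p-values

def gen_bum_pvalues(n: int, lam: float, a: float, seed: int = 0) -> np.ndarray:
    """Sample p-values from the beta-uniform mixture lam*U(0,1) + (1-lam)*Beta(a,1)."""
    if not 0 <= lam <= 1:
        raise ValueError("lam must lie in [0, 1]")
    if not 0 < a < 1:
        raise ValueError("a must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    from_noise = rng.random(n) < lam
    p = np.empty(n)
    # inverse-CDF draws on (0, 1]: u in (0, 1]
    u = 1.0 - rng.random(n)
    p[from_noise] = u[from_noise]
    p[~from_noise] = u[~from_noise] ** (1.0 / a)  # Beta(a, 1) quantile
    return p


# ---------------------------------------------------------------------------
# DamID

def _plant_gatc_sequence(chrom_len: int, gatc_spacing: int, rng: np.random.Generator) -> str:
    """Random chromosome whose only GATC motifs sit at near-regular spacing."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=chrom_len)
    motif = np.array(list("GATC"))
    planted: list[int] = []
    pos = int(rng.integers(gatc_spacing))
    while pos + 4 <= chrom_len:
        seq[pos : pos + 4] = motif
        planted.append(pos)
        jitter = int(rng.integers(-gatc_spacing // 10, gatc_spacing // 10 + 1))
        pos += max(8, gatc_spacing + jitter)
    planted_set = set(planted)
    s = "".join(seq)
    # remove spurious motifs created by the random background
    while True:
        spurious = []
        i = s.find("GATC")
        while i != -1:
            if i not in planted_set:
                spurious.append(i)
            i = s.find("GATC", i + 1)
        spurious = [
            i
            for i in spurious
            if all(abs(i - p) >= 4 for p in planted_set)
        ]
        if not spurious:
            break
        arr = np.array(list(s))
        for i in spurious:
            cur = arr[i + 1]
            arr[i + 1] = rng.choice([b for b in "ACGT" if b not in (cur, "A")])
        s = "".join(arr)
    return s


def gen_damid_dataset(
    chrom_len: int = 100_000,
    gatc_spacing: int = 200,
    lads: DamidTruth | None = None,
    reads_per_condition: int = 200_000,
    seed: int = 0,
    chrom: str = "chrS",
) -> DamidDataset:
    """Synthetic DamID experiment: genome, fusion reads and control reads.

    Control read starts are uniform over the chromosome; fusion
    (Dam-laminB1) reads are sampled with weight multiplied by
    ``lads.enrichment`` inside the planted lamina-associated intervals.
    """
    if gatc_spacing < 8:
        raise ValueError("gatc_spacing must be >= 8")
    if reads_per_condition <= 0:
        raise ValueError("reads_per_condition must be positive")
    if lads is None:
        lads = DamidTruth(
            lad_intervals=[
                (chrom, int(chrom_len * 0.15), int(chrom_len * 0.25)),
                (chrom, int(chrom_len * 0.60), int(chrom_len * 0.70)),
            ],
            enrichment=4.0,
        )
    lads.validate({chrom: chrom_len})

    rng = np.random.default_rng(seed)
    sequence = _plant_gatc_sequence(chrom_len, gatc_spacing, rng)

    weights = np.ones(chrom_len)
    for c, start, end in lads.lad_intervals:
        if c == chrom:
            weights[start:end] *= lads.enrichment
    probs = weights / weights.sum()
    fusion = np.sort(rng.choice(chrom_len, size=reads_per_condition, p=probs))
    control = np.sort(rng.integers(0, chrom_len, size=reads_per_condition))
    return DamidDataset(chrom, sequence, fusion, control, truth=lads)


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    """Write sequences as single-line-wrapped FASTA (``width`` columns)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_bed_starts(path: str | Path, chrom: str, starts: np.ndarray) -> None:
    """Write read start positions as 3-column BED (start, start+1; 0-based)."""
    with open(path, "w") as fh:
        for s in np.asarray(starts, dtype=int):
            fh.write(f"{chrom}\t{s}\t{s + 1}\n")


# ---------------------------------------------------------------------------
# imaging

def gen_voxel_pair(
    shape: tuple[int, int, int] = (16, 32, 32),
    overlap_frac: float = 0.5,
    seed: int = 0,
    fg_frac: float = 0.05,
    fg_intensity: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two 3D images whose foreground supports overlap by an exact fraction.

    Both foregrounds contain the same number of voxels; they share exactly
    ``round(overlap_frac * |A|)`` voxels. Foreground voxels take intensity
    ``fg_intensity``, background 0. The returned mask marks a centred
    spherical-shell "membrane" region.
    """
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    if np.prod(shape) == 0:
        raise ValueError("empty shape")
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    n_fg = max(1, int(round(fg_frac * n_vox)))
    n_shared = int(round(overlap_frac * n_fg))
    if 2 * n_fg - n_shared > n_vox:
        raise ValueError("foregrounds do not fit in the volume")

    perm = rng.permutation(n_vox)
    a_idx = perm[:n_fg]
    shared = a_idx[:n_shared]
    b_only = perm[n_fg : 2 * n_fg - n_shared]
    b_idx = np.concatenate([shared, b_only])

    a = np.zeros(n_vox)
    b = np.zeros(n_vox)
    a[a_idx] = fg_intensity
    b[b_idx] = fg_intensity
    a = a.reshape(shape)
    b = b.reshape(shape)

    centre = [(d - 1) / 2 for d in shape]
    grids = np.meshgrid(*[np.arange(d) for d in shape], indexing="ij")
    r = np.sqrt(sum(((g - c) / max(c, 0.5)) ** 2 for g, c in zip(grids, centre)))
    mask = (r >= 0.6) & (r <= 0.9)
    return a, b, mask


# ---------------------------------------------------------------------------
# plain-text truth serialisation

def truth_to_json(truth, path: str | Path) -> None:
    """Serialise a truth object (LfqTruth/NetworkTruth/DamidTruth) to JSON."""
    if isinstance(truth, LfqTruth):
        payload = {
            "kind": "lfq",
            "differential_ids": sorted(truth.differential_ids),
            "true_log2fc": truth.true_log2fc.to_dict(),
        }
    elif isinstance(truth, NetworkTruth):
        payload = {"kind": "network", "planted_members": sorted(truth.planted_members)}
    elif isinstance(truth, DamidTruth):
        payload = {
            "kind": "damid",
            "lad_intervals": [list(iv) for iv in truth.lad_intervals],
            "enrichment": truth.enrichment,
        }
    else:
        raise TypeError(f"unsupported truth object {type(truth)!r}")
    Path(path).write_text(json.dumps(payload, indent=1))
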