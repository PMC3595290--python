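"""Synthetic three-strain DGE tag libraries with known ground truth.

Emulates the study design the pipeline targets: two homokaryotic parent
strains (P1, P2) whose alleles differ by SNPs, and their heterokaryon
(H) carrying both parental nuclei.  Each gene emits tags from the
3'-most CATG-anchored window of the emitting allele (oligo-dT capture
plus NlaIII/MmeI digestion releases only the 3'-terminal fragment);
the heterokaryon splits each gene's tags evenly between the two
parental alleles.  Planted structure:

* strain-specific silent genes (zero rate in one parent);
* "complementation-boost" genes: low expression in both parents,
  boosted in the heterokaryon;
* per-base sequencing errors, N-containing tags, adaptor contamination,
  and planted copy-number-1 junk tags, so the QC ledger has work to do.

Counts are Poisson by default, or negative binomial with variance
mu + dispersion * mu^2 when ``dispersion`` > 0 (libraries are single
replicates, so overdispersion is a knob, not a fitted quantity).
The truth table records every planted label, allowing end-to-end
recovery tests that share no code with the classifiers they validate.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from dgetag.index import DEFAULT_TAG_LENGTH, three_prime_tag
from dgetag.library import TagLibrary

STRAIN_P1, STRAIN_P2, STRAIN_H = "P1", "P2", "H"

#: synthetic sequencing-adaptor tags (the real adaptor sequences are
#: instrument library-prep details; any fixed foreign sequence works)
ADAPTOR_SEQUENCES = (
    "CATGCGGCCGCTTAAGGGTCA",
    "CATGTCTAGAGGATCCAAGCT",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")


@dataclass
class SimulationParams:
    """Generator knobs; defaults mirror the profiled study's scale.

    Rates are probabilities in [0, 1]; ``library_size`` is the expected
    total tag count per strain; expression rates are in tags per million.
    """

    n_genes: int = 11534
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 300.0
    library_size: int = 5_900_000
    base_error_rate: float = 0.005
    n_rate: float = 0.003
    adaptor_rate: float = 5e-5
    singleton_noise: int = 30_000
    frac_silent_p1: float = 0.08
    frac_silent_p2: float = 0.08
    frac_boost: float = 0.01
    boost_factor: float = 30.0
    snp_rate: float = 0.001
    dispersion: float = 0.0
    catg_fraction: float = 0.95
    tag_length: int = DEFAULT_TAG_LENGTH
    expression_sigma: float = 1.5  # log-normal spread of baseline rates
    strain_sigma: float = 0.6  # extra log-normal P1-vs-P2 rate divergence
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "base_error_rate": self.base_error_rate,
            "n_rate": self.n_rate,
            "adaptor_rate": self.adaptor_rate,
            "frac_silent_p1": self.frac_silent_p1,
            "frac_silent_p2": self.frac_silent_p2,
            "frac_boost": self.frac_boost,
            "snp_rate": self.snp_rate,
            "catg_fraction": self.catg_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.frac_silent_p1 + self.frac_silent_p2 + self.frac_boost > 1.0:
            raise ValueError("silent + boost fractions exceed 1")
        if self.tag_length < 5:
            raise ValueError("tag_length must be >= 5")
        if self.dispersion < 0 or self.boost_factor <= 0 or self.singleton_noise < 0:
            raise ValueError("dispersion/boost_factor/singleton_noise out of range")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Per-gene ground truth: planted rates, labels, and allele tags."""

    table: pd.DataFrame  # index: gene id
    params: SimulationParams = field(repr=False, default=None)

    def genes_in_category(self, cat: str) -> pd.Index:
        return self.table.index[self.table["category"] == cat]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t")


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genes(params: SimulationParams) -> dict[str, str]:
    """Random transcript models, most carrying a usable CATG tag site.

    A ``catg_fraction`` share of genes is guaranteed at least one CATG
    with a full tag window downstream (planted at the 3' end when the
    random sequence lacks one); the remainder is scrubbed of CATG so the
    pipeline sees tag-less ("unmeasurable") genes too.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_genes
    if n == 0:
        return {}
    width = len(str(n))
    min_len = max(25, params.tag_length)
    lengths = np.maximum(
        min_len,
        np.rint(rng.normal(params.gene_length_mean, params.gene_length_sd, size=n)).astype(int),
    )
    taggable = np.zeros(n, dtype=bool)
    taggable[rng.permutation(n)[: int(round(params.catg_fraction * n))]] = True

    genes: dict[str, str] = {}
    for i in range(n):
        codes = rng.integers(0, 4, size=lengths[i], dtype=np.int64)
        seq = _decode(codes)
        if taggable[i]:
            if three_prime_tag(seq, params.tag_length) is None:
                pos = lengths[i] - params.tag_length
                seq = seq[:pos] + "CATG" + seq[pos + 4 :]
        else:
            while (hit := seq.find("CATG")) != -1:
                seq = seq[: hit + 3] + "T" + seq[hit + 4 :]
        genes[f"G{i + 1:0{width}d}"] = seq
    return genes


def _mutate_allele(seq: str, snp_rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    if snp_rate <= 0:
        return seq, []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(len(seq)) < snp_rate)
    positions = []
    lookup = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    for p in idx:
        base = lookup.get(int(codes[p]))
        if base is None:
            continue
        codes[p] = _BASES[(base + int(rng.integers(1, 4))) % 4]
        positions.append(int(p))
    return codes.tobytes().decode(), positions


def _draw_counts(
    lam: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(lam)
    shape = 1.0 / dispersion
    counts = np.zeros_like(lam, dtype=np.int64)
    pos = lam > 0
    p = shape / (shape + lam[pos])
    counts[pos] = rng.negative_binomial(shape, p)
    return counts


def _corrupt_and_count(
    tags: list[str],
    counts: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Counter:
    """Turn per-tag emission counts into an observed-tag multiset.

    Each emitted copy is independently replaced by an N-containing
    version (n_rate) or an adaptor (adaptor_rate); surviving copies
    acquire per-base substitution errors at base_error_rate.  Copy
    totals are conserved exactly.
    """
    L = params.tag_length
    p_err = 1.0 - (1.0 - params.base_error_rate) ** L
    observed: Counter = Counter()
    tag_matrix = np.frombuffer("".join(tags).encode(), dtype=np.uint8).reshape(-1, L)

    err_rows: list[int] = []
    err_counts: list[int] = []
    n_rows: list[int] = []
    n_counts: list[int] = []
    adaptor_copies = 0
    for i, (tag, c) in enumerate(zip(tags, counts)):
        c = int(c)
        if c == 0:
            continue
        n_n, n_ad, rest = rng.multinomial(
            c, [params.n_rate, params.adaptor_rate, 1.0 - params.n_rate - params.adaptor_rate]
        )
        adaptor_copies += int(n_ad)
        if n_n:
            n_rows.append(i)
            n_counts.append(int(n_n))
        n_err = int(rng.binomial(rest, p_err)) if rest else 0
        if n_err:
            err_rows.append(i)
            err_counts.append(n_err)
        if rest - n_err:
            observed[tag] += int(rest - n_err)

    # per-copy substitution errors, vectorised over all erroneous copies
    if err_rows:
        rows = np.repeat(np.array(err_rows), np.array(err_counts))
        mat = tag_matrix[rows].copy()
        mask = rng.random(mat.shape) < params.base_error_rate
        empty = ~mask.any(axis=1)  # copies drawn as erroneous get >= 1 error
        mask[np.flatnonzero(empty), rng.integers(0, L, size=int(empty.sum()))] = True
        flat = mat[mask]
        code = np.searchsorted(_BASES, flat)  # ACGT are sorted ascii
        mat[mask] = _BASES[(code + rng.integers(1, 4, size=flat.size)) % 4]
        blob = mat.tobytes()
        observed.update(blob[j * L : (j + 1) * L].decode() for j in range(mat.shape[0]))

    # N-containing copies: one random position overwritten with N
    if n_rows:
        rows = np.repeat(np.array(n_rows), np.array(n_counts))
        mat = tag_matrix[rows].copy()
        mat[np.arange(mat.shape[0]), rng.integers(0, L, size=mat.shape[0])] = _N
        blob = mat.tobytes()
        observed.update(blob[j * L : (j + 1) * L].decode() for j in range(mat.shape[0]))

    if adaptor_copies:
        adaptors = [a[:L].ljust(L, "A") for a in ADAPTOR_SEQUENCES]
        split = rng.multinomial(adaptor_copies, [1.0 / len(adaptors)] * len(adaptors))
        for a, c in zip(adaptors, split):
            if c:
                observed[a] += int(c)
    return observed


def _append_singletons(
    observed: Counter, n_singletons: int, tag_length: int, rng: np.random.Generator
) -> None:
    """Add exactly n distinct junk tags with copy number 1."""
    added = 0
    while added < n_singletons:
        batch = max(64, 2 * (n_singletons - added))
        codes = rng.integers(0, 4, size=(batch, tag_length))
        blob = _BASES[codes].tobytes()
        for j in range(batch):
            tag = blob[j * tag_length : (j + 1) * tag_length].decode()
            if tag not in observed:
                observed[tag] = 1
                added += 1
                if added == n_singletons:
                    break


def simulate_triad(
    genes: dict[str, str], params: SimulationParams
) -> tuple[dict[str, TagLibrary], SyntheticTruth]:
    """Simulate P1, P2 and heterokaryon tag libraries plus ground truth.

    Planted rate structure (tags per million): baseline log-normal
    rates, independent silent sets per parent, heterokaryon rates equal
    to the parental mean except for boost genes (low in both parents,
    multiplied by ``boost_factor`` in H).  Truth categories follow the
    complementation definitions: A (silent in P1, high in P2), B
    (mirror), C (boost genes).
    """
    params.validate()
    if not genes:
        raise ValueError("gene set must be non-empty")
    rng = np.random.default_rng([params.seed, 1])
    noise_rng = np.random.default_rng([params.seed, 2])  # junk singletons: own stream
    ids = list(genes)
    n = len(ids)

    # parental alleles and their emitted (3'-most) tags
    tag1: list[str | None] = []
    tag2: list[str | None] = []
    snp_positions: list[str] = []
    for g in ids:
        allele2, pos = _mutate_allele(genes[g], params.snp_rate, rng)
        tag1.append(three_prime_tag(genes[g], params.tag_length))
        tag2.append(three_prime_tag(allele2, params.tag_length))
        snp_positions.append(",".join(map(str, pos)))
    measurable = np.array([t1 is not None and t2 is not None for t1, t2 in zip(tag1, tag2)])

    # planted expression rates (TPM)
    base = rng.lognormal(np.log(30.0), params.expression_sigma, size=n)
    strain_shift = rng.lognormal(0.0, params.strain_sigma, size=n)
    perm = rng.permutation(n)
    k1 = int(round(params.frac_silent_p1 * n))
    k2 = int(round(params.frac_silent_p2 * n))
    k3 = int(round(params.frac_boost * n))
    silent1, silent2, boost = perm[:k1], perm[k1 : k1 + k2], perm[k1 + k2 : k1 + k2 + k3]

    r1 = base.copy()
    r2 = base * strain_shift
    r1[silent1] = 0.0
    r2[silent2] = 0.0
    r1[~measurable] = 0.0
    r2[~measurable] = 0.0
    for r in (r1, r2):  # express rates on the TPM scale
        total = r.sum()
        if total > 0:
            r *= 1e6 / total
    live_boost = boost[measurable[boost]]
    r1[live_boost] = rng.uniform(2.0, 15.0, size=live_boost.size)
    r2[live_boost] = rng.uniform(2.0, 15.0, size=live_boost.size)
    rh = (r1 + r2) / 2.0
    rh[live_boost] *= params.boost_factor

    category = np.array(["none"] * n, dtype=object)
    category[silent1[(r2[silent1] >= 50.0)]] = "A"
    category[silent2[(r1[silent2] >= 50.0)]] = "B"
    category[live_boost] = "C"

    libraries: dict[str, TagLibrary] = {}
    for strain, rates in ((STRAIN_P1, r1), (STRAIN_P2, r2), (STRAIN_H, rh)):
        lam = rates / 1e6 * params.library_size
        counts = _draw_counts(lam, params.dispersion, rng)
        emit_tags: list[str] = []
        emit_counts: list[int] = []
        for i in range(n):
            c = int(counts[i])
            if c == 0 or tag1[i] is None or tag2[i] is None:
                continue
            if strain == STRAIN_P1:
                emit_tags.append(tag1[i])
                emit_counts.append(c)
            elif strain == STRAIN_P2:
                emit_tags.append(tag2[i])
                emit_counts.append(c)
            else:  # heterokaryon: copies split between the two nuclei
                c1 = int(rng.binomial(c, 0.5))
                if c1:
                    emit_tags.append(tag1[i])
                    emit_counts.append(c1)
                if c - c1:
                    emit_tags.append(tag2[i])
                    emit_counts.append(c - c1)
        observed = (
            _corrupt_and_count(emit_tags, np.array(emit_counts), params, rng)
            if emit_tags
            else Counter()
        )
        _append_singletons(observed, params.singleton_noise, params.tag_length, noise_rng)
        libraries[strain] = TagLibrary(dict(observed), name=strain)

    floored = lambda r: np.maximum(r, 0.01)
    truth = pd.DataFrame(
        {
            "rate_p1": r1,
            "rate_p2": r2,
            "rate_h": rh,
            "category": category,
            "measurable": measurable,
            "tag_p1": [t or "" for t in tag1],
            "tag_p2": [t or "" for t in tag2],
            "snp_positions": snp_positions,
            "de_p1_p2": np.abs(np.log2(floored(r2) / floored(r1))) > 2,
            "de_p1_h": np.abs(np.log2(floored(rh) / floored(r1))) > 2,
            "de_p2_h": np.abs(np.log2(floored(rh) / floored(r2))) > 2,
        },
        index=pd.Index(ids, name="gene"),
    )
    return libraries, SyntheticTruth(table=truth, params=params)


def write_fasta(genes: dict[str, str], path: str | os.PathLike) -> None:
    """Write gene models as FASTA (wrapped at 70 columns)."""
    with open(path, "w") as fh:
        for gene, seq in genes.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
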