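"""Synthetic 2x-4x breeding datasets: genotypes, crosses, trials, phenotypes.

The generator emulates the structure of a triploid banana breeding trial:

* a diploid parental panel of bi-allelic SNPs (no linkage: markers segregate
  independently, which is sufficient for the single-marker expectations the
  model rests on);
* tetraploid parents as colchicine-doubled diploids (dosage doubling);
* triploid progeny receiving one Mendelian diploid gamete and one polysomic
  tetraploid gamete (random bivalent pairing, no double reduction);
* unbalanced full-sib family sizes;
* an augmented trial design of blocks holding 56 hybrids plus 8 control
  plants (five replicates of a Cavendish-type check and one plant each of
  three further controls), blocks nested in trials;
* three crop cycles per plant with errors drawn from an unstructured 3x3
  residual covariance; and
* genetic values decomposable into 2x GCA, 4x GCA, SCA and within-cross
  deviations, either drawn directly from target variance components
  (``engine="gaussian"``) or built from QTL effects on simulated triploid
  dosages and decomposed by exact conditional expectations over the gamete
  distribution (``engine="genomic"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import ParentGenotypes
from .kinship import dominance_regressor, expected_hybrid_regressor
from .tables import StudyTables

CONTROL_VARIETIES = ("Cavendish", "PisangCeylan", "PisangMadu", "Calcutta4")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Variance defaults mirror the qualitative findings on real 2x-4x trials:
    the tetraploid GCA dominates the diploid GCA (here 3:1), the SCA share
    is small, the within-cross component is substantial, and errors of the
    same plant are positively correlated across cycles.
    """

    n_parents2x: int = 15
    n_parents4x: int = 15
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.95)
    n_crosses: int = 40
    family_sizes: int | tuple[int, int] | list[int] | None = None
    engine: str = "gaussian"
    # gaussian engine targets
    sigma2_D: float = 0.3
    sigma2_T: float = 0.9
    sigma2_DT: float = 0.1
    sigma2_H: float = 0.5
    # genomic engine
    n_qtl: int = 100
    dominance_share: float = 0.0
    # fixed effects and residual
    mu: float = 10.0
    block_sd: float = 1.0
    cycle_effects: tuple[float, float, float] = (0.0, 0.5, -0.3)
    R: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.5, 0.4], [0.5, 1.1, 0.5], [0.4, 0.5, 1.2]]))
    # trial layout
    block_hybrids: int = 56
    block_controls: int = 8
    n_check_replicates: int = 5
    trial_blocks: int = 4
    controls: tuple[str, ...] = CONTROL_VARIETIES
    trait_name: str = "trait"
    traits: tuple[str, ...] | None = None  # multi-trait: overrides trait_name
    seed: int = 0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if np.linalg.eigvalsh(self.R).min() <= 0:
            raise ValueError("residual covariance R must be positive definite")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("degenerate allele-frequency range")
        if self.block_hybrids <= 0:
            raise ValueError("block capacity must be positive")
        if self.n_check_replicates + len(self.controls) - 1 != self.block_controls:
            raise ValueError(
                "block_controls must equal n_check_replicates + number of "
                "non-check controls"
            )


@dataclass
class SimulatedTruth:
    """Exact generating quantities of a simulated dataset."""

    clonal_values: pd.Series          # hybrid -> genetic deviation from mean
    gca2: pd.Series                   # 2x parent effects
    gca4: pd.Series                   # 4x parent effects
    sca: pd.Series                    # (2x, 4x) cross effects
    within: pd.Series                 # hybrid within-cross deviations
    cross_means: pd.Series            # (2x, 4x) -> gca2 + gca4 + sca
    control_values: pd.Series
    realized_components: dict[str, float]
    hybrid_dosages: np.ndarray | None = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: ParentGenotypes
    tables: StudyTables
    truths: dict[str, SimulatedTruth]

    @property
    def truth(self) -> SimulatedTruth:
        """Truth of the first (or only) simulated trait."""
        return next(iter(self.truths.values()))


# -- building blocks -------------------------------------------------------


def simulate_parent_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ParentGenotypes:
    """Diploid parental panel: dosages ~ Binomial(2, f), f uniform in range.

    Monomorphic realizations are redrawn so the returned panel never carries
    a marker with frequency 0 or 1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_parents2x + config.n_parents4x
    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=config.n_markers)
    dos = rng.binomial(2, f, size=(n, config.n_markers))
    for _ in range(100):
        tot = dos.sum(axis=0)
        mono = (tot == 0) | (tot == 2 * n)
        if not mono.any():
            break
        f[mono] = rng.uniform(lo, hi, size=mono.sum())
        dos[:, mono] = rng.binomial(2, f[mono], size=(n, mono.sum()))
    else:
        raise RuntimeError("could not draw a polymorphic panel")
    ids = [f"D{i + 1:03d}" for i in range(config.n_parents2x)] + [
        f"T{i + 1:03d}" for i in range(config.n_parents4x)
    ]
    m = config.n_markers
    return ParentGenotypes(
        parent_ids=ids,
        marker_ids=[f"chr1:{100 * (j + 1)}" for j in range(m)],
        chrom=np.array(["chr1"] * m),
        pos=np.array([100 * (j + 1) for j in range(m)], dtype=int),
        dosages=dos.astype(np.int8),
    )


def simulate_cross_progeny(
    parent2x: np.ndarray,
    parent4x_base: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Triploid progeny dosages of one 2x-4x cross, markers independent.

    The diploid gamete carries Bernoulli(x2 / 2) alternative alleles; the
    tetraploid gamete is two chromosomes drawn without replacement from the
    four copies of the doubled genotype (hypergeometric), i.e. polysomic
    inheritance with random bivalent pairing and no double reduction.
    """
    if n <= 0:
        raise ValueError("progeny count must be positive")
    x2 = np.asarray(parent2x, dtype=int)
    x4b = np.asarray(parent4x_base, dtype=int)
    if x2.min() < 0 or x2.max() > 2 or x4b.min() < 0 or x4b.max() > 2:
        raise ValueError("base dosages must be in {0, 1, 2}")
    m = x2.size
    gam2 = rng.binomial(1, np.broadcast_to(x2 / 2.0, (n, m)))
    good = np.broadcast_to(2 * x4b, (n, m))
    gam4 = rng.hypergeometric(good, 4 - good, 2)
    return (gam2 + gam4).astype(np.int8)


def _family_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    fs = config.family_sizes
    if fs is None:
        # skewed sizes emulating 1..188 progeny per cross
        raw = np.ceil(rng.lognormal(mean=2.7, sigma=1.1, size=config.n_crosses))
        return np.clip(raw, 1, 188).astype(int)
    if isinstance(fs, int):
        return np.full(config.n_crosses, fs, dtype=int)
    if isinstance(fs, tuple):
        return rng.integers(fs[0], fs[1] + 1, size=config.n_crosses)
    sizes = np.asarray(list(fs), dtype=int)
    if sizes.size != config.n_crosses:
        raise ValueError("family_sizes list must match n_crosses")
    return sizes


def _draw_crosses(config: SimulationConfig, rng: np.random.Generator):
    """Random (2x, 4x) pairs covering every parent at least once."""
    p2 = [f"D{i + 1:03d}" for i in range(config.n_parents2x)]
    p4 = [f"T{i + 1:03d}" for i in range(config.n_parents4x)]
    if config.n_crosses > len(p2) * len(p4):
        raise ValueError("more crosses requested than distinct parent pairs")
    pairs = [(u, v) for u in p2 for v in p4]
    rng.shuffle(pairs)
    chosen: list[tuple[str, str]] = []
    # greedily cover all parents first so GCA levels are estimable
    for u in p2:
        v = p4[rng.integers(len(p4))]
        if (u, v) not in chosen:
            chosen.append((u, v))
    for v in p4:
        if not any(c[1] == v for c in chosen):
            u = p2[rng.integers(len(p2))]
            if (u, v) not in chosen:
                chosen.append((u, v))
    for pair in pairs:
        if len(chosen) >= config.n_crosses:
            break
        if pair not in chosen:
            chosen.append(pair)
    return chosen[: config.n_crosses]


def _genomic_truth(
    config: SimulationConfig,
    geno: ParentGenotypes,
    crosses: list[tuple[str, str]],
    sizes: np.ndarray,
    rng: np.random.Generator,
):
    """QTL-based clonal values with an exact GCA/SCA/within decomposition.

    Cross means are closed-form expectations over the gamete distribution;
    GCA effects are marginal means over the virtual complete factorial of
    the parents used in the design, so gca2 + gca4 + sca + within reproduces
    each hybrid's clonal value exactly.
    """
    qtl = rng.choice(geno.n_markers, size=min(config.n_qtl, geno.n_markers),
                     replace=False)
    a = rng.normal(0.0, 1.0, size=qtl.size)
    d = np.zeros(qtl.size)
    if config.dominance_share > 0:
        d = rng.normal(0.0, np.sqrt(config.dominance_share), size=qtl.size)
    f = geno.freqs[qtl]

    p2 = sorted({u for u, _ in crosses})
    p4 = sorted({v for _, v in crosses})
    x2 = geno.dosages[geno.index_of(p2)][:, qtl].astype(float)
    x4 = 2.0 * geno.dosages[geno.index_of(p4)][:, qtl].astype(float)
    # factorial cross means: additive on E(X), dominance on Q_uv
    mu = np.zeros((len(p2), len(p4)))
    for j, v in enumerate(p4):
        q, ex, _ = expected_hybrid_regressor(x2, x4[j][None, :], f[None, :])
        mu[:, j] = ex @ a + q @ d
    grand = mu.mean()
    g2 = mu.mean(axis=1) - grand
    g4 = mu.mean(axis=0) - grand
    sca_mat = mu - grand - g2[:, None] - g4[None, :]

    gca2 = pd.Series(g2, index=p2)
    gca4 = pd.Series(g4, index=p4)
    sca = pd.Series({(u, v): sca_mat[p2.index(u), p4.index(v)]
                     for u, v in crosses})

    hybrid_ids, clonal, within, dosages = [], [], [], []
    for (u, v), nfam in zip(crosses, sizes):
        xu = geno.dosages[geno.index_of([u])[0], qtl]
        xv = geno.dosages[geno.index_of([v])[0], qtl]
        X = simulate_cross_progeny(xu, xv, int(nfam), rng).astype(float)
        gval = X @ a + dominance_regressor(X, 3, f[None, :]) @ d - grand
        muv = mu[p2.index(u), p4.index(v)] - grand
        for k in range(int(nfam)):
            hid = f"H_{u}x{v}_{k + 1:03d}"
            hybrid_ids.append(hid)
            clonal.append(gval[k])
            within.append(gval[k] - muv)
        dosages.append(X)
    return (gca2, gca4, sca,
            pd.Series(clonal, index=hybrid_ids),
            pd.Series(within, index=hybrid_ids),
            np.concatenate(dosages, axis=0) if dosages else None)


def _gaussian_truth(
    config: SimulationConfig,
    crosses: list[tuple[str, str]],
    sizes: np.ndarray,
    rng: np.random.Generator,
):
    p2 = sorted({u for u, _ in crosses})
    p4 = sorted({v for _, v in crosses})
    gca2 = pd.Series(rng.normal(0, np.sqrt(config.sigma2_D), len(p2)), index=p2)
    gca4 = pd.Series(rng.normal(0, np.sqrt(config.sigma2_T), len(p4)), index=p4)
    sca = pd.Series(rng.normal(0, np.sqrt(config.sigma2_DT), len(crosses)),
                    index=pd.Index(crosses))
    hybrid_ids, clonal, within = [], [], []
    for (u, v), nfam in zip(crosses, sizes):
        h = rng.normal(0, np.sqrt(config.sigma2_H), int(nfam))
        base = gca2[u] + gca4[v] + sca[(u, v)]
        for k in range(int(nfam)):
            hid = f"H_{u}x{v}_{k + 1:03d}"
            hybrid_ids.append(hid)
            clonal.append(base + h[k])
            within.append(h[k])
    return (gca2, gca4, sca,
            pd.Series(clonal, index=hybrid_ids),
            pd.Series(within, index=hybrid_ids), None)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic study under a single master seed.

    All randomness flows from ``config.seed`` through named substreams, so
    two runs with the same configuration are identical byte for byte.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ["panel", "crosses", "design"], root.spawn(3))}
    traits = tuple(config.traits) if config.traits else (config.trait_name,)
    trait_seeds = root.spawn(2 * len(traits))

    geno = simulate_parent_panel(config, streams["panel"])
    crosses = _draw_crosses(config, streams["crosses"])
    sizes = _family_sizes(config, streams["crosses"])

    # pedigree
    ped_rows = []
    for (u, v), nfam in zip(crosses, sizes):
        for k in range(int(nfam)):
            ped_rows.append((f"H_{u}x{v}_{k + 1:03d}", u, v, f"{u}x{v}"))
    pedigree = pd.DataFrame(ped_rows, columns=[
        "hybrid_id", "parent2x_id", "parent4x_id", "family_id"])

    # trial design: blocks of hybrids + controls, blocks nested in trials
    rngd = streams["design"]
    hybrids = pedigree["hybrid_id"].to_numpy().copy()
    rngd.shuffle(hybrids)
    n_blocks = int(np.ceil(len(hybrids) / config.block_hybrids))
    if n_blocks == 0:
        raise ValueError("no hybrids to lay out")
    block_effects = rngd.normal(0, config.block_sd, n_blocks)
    plants = []  # (plant_id, type, trial, block, replicate, variety, block#)
    for b in range(n_blocks):
        trial = f"TR{b // config.trial_blocks + 1:02d}"
        block = f"B{b + 1:03d}"
        chunk = hybrids[b * config.block_hybrids:(b + 1) * config.block_hybrids]
        plants += [(h, "breed", trial, block, 1, None, b) for h in chunk]
        check, *others = config.controls
        plants += [(f"CTL_{check}_{block}_r{r}", "control", trial, block, r,
                    check, b) for r in range(1, config.n_check_replicates + 1)]
        plants += [(f"CTL_{c}_{block}_r1", "control", trial, block, 1, c, b)
                   for c in others]

    Lr = np.linalg.cholesky(config.R)
    cyc = np.asarray(config.cycle_effects, dtype=float)
    rows = []
    truths: dict[str, SimulatedTruth] = {}
    for ti, trait in enumerate(traits):
        rng_gen = np.random.default_rng(trait_seeds[2 * ti])
        rng_err = np.random.default_rng(trait_seeds[2 * ti + 1])
        if config.engine == "genomic":
            gca2, gca4, sca, clonal, within, hdos = _genomic_truth(
                config, geno, crosses, sizes, rng_gen)
        elif config.engine == "gaussian":
            gca2, gca4, sca, clonal, within, hdos = _gaussian_truth(
                config, crosses, sizes, rng_gen)
        else:
            raise ValueError(f"unknown engine {config.engine!r}")
        control_values = pd.Series(
            rng_gen.normal(0, np.sqrt(config.sigma2_H), len(config.controls)),
            index=list(config.controls))
        for pid, typ, trial, block, rep, variety, b in plants:
            gval = (control_values[variety] if typ == "control"
                    else clonal[pid])
            e = Lr @ rng_err.standard_normal(3)
            for c in (1, 2, 3):
                rows.append((pid, typ, trial, block, c, rep, trait,
                             config.mu + block_effects[b] + cyc[c - 1]
                             + gval + e[c - 1], variety))
        realized = {
            "sigma2_D": float(gca2.var(ddof=1)) if len(gca2) > 1 else 0.0,
            "sigma2_T": float(gca4.var(ddof=1)) if len(gca4) > 1 else 0.0,
            "sigma2_DT": float(sca.var(ddof=1)) if len(sca) > 1 else 0.0,
            "sigma2_H": float(within.var(ddof=1)) if len(within) > 1 else 0.0,
        }
        truths[trait] = SimulatedTruth(
            clonal_values=clonal, gca2=gca2, gca4=gca4, sca=sca,
            within=within,
            cross_means=pd.Series({(u, v): gca2[u] + gca4[v] + sca[(u, v)]
                                   for u, v in crosses}),
            control_values=control_values,
            realized_components=realized,
            hybrid_dosages=hdos,
        )

    phenotypes = pd.DataFrame(rows, columns=[
        "plant_id", "type", "trial_id", "block_id", "cycle", "replicate",
        "trait", "value", "control_variety"])
    tables = StudyTables(pedigree=pedigree, phenotypes=phenotypes)
    return SimulatedDataset(config=config, genotypes=geno, tables=tables,
                            truths=truths)


def write_dataset(data: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Persist a simulated dataset in the formats the pipeline consumes."""
    import os

    from .genotypes import write_parent_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "parents.vcf"),
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "truth": os.path.join(outdir, "truth.csv"),
    }
    write_parent_vcf(data.genotypes, paths["vcf"])
    data.tables.pedigree.to_csv(paths["pedigree"], index=False)
    data.tables.phenotypes.to_csv(paths["phenotypes"], index=False)
    data.truth.clonal_values.rename("clonal_value").to_csv(paths["truth"])
    return paths


def null_config(**overrides) -> SimulationConfig:
    """A configuration with all genetic variances zero (calibration runs)."""
    base = dict(sigma2_D=0.0, sigma2_T=0.0, sigma2_DT=0.0, sigma2_H=0.0)
    base.update(overrides)
    return SimulationConfig(**base)

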