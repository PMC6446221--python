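"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic under a fixed seed and returns, next to the
data, the ground truth used to produce it (dose-response parameters, planted
causal markers, planted cliques), so that parameter-recovery and power tests
can compare estimates against known values.

The default study conditions emulate a 36-strain yeast collection screened
in 13 stress conditions at 4-7 inhibitory levels with duplicate wells
(>5400 curves), monitored for ~66 h.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "StrainRecord",
    "TruthSet",
    "gen_strains",
    "gen_growth_curves",
    "gen_genotypes",
    "gen_cnv",
    "gen_genes",
    "gen_network",
    "gen_metabolome",
    "logistic_curve",
    "dose_factor",
    "strain_frame",
]

CATEGORY_SUBCATS = {
    "industrial": ("bioethanol", "brewing", "food"),
    "environmental": ("soil", "plant", "animal"),
    "laboratory": ("lab",),
    "clinical": ("clinical",),
}
# approximate proportions of the emulated collection: 17/13/4/2 of 36
CATEGORY_WEIGHTS = {
    "industrial": 17 / 36,
    "environmental": 13 / 36,
    "laboratory": 4 / 36,
    "clinical": 2 / 36,
}
GEOGRAPHIES = ("Brazil", "Europe", "North America", "Asia", "Africa", "Oceania")

#: 16 nuclear chromosomes with compact toy lengths (bp)
DEFAULT_CHROM_LENGTHS = {
    f"chr{r}": length
    for r, length in zip(
        ("I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI").split(),
        np.linspace(60_000, 300_000, 16).astype(int).tolist(),
    )
}


@dataclass
class StrainRecord:
    strain_id: str
    category: str
    subcategory: str
    geography: str
    ploidy: int
    bin_group: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_SUBCATS:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcategory not in CATEGORY_SUBCATS[self.category]:
            raise ValueError(
                f"subcategory {self.subcategory!r} inconsistent with {self.category!r}"
            )
        if self.ploidy < 1:
            raise ValueError("ploidy must be positive")


@dataclass
class TruthSet:
    """Ground truth behind a synthetic dataset."""

    strain_params: pd.DataFrame | None = None   # per-strain baseline growth
    dose_response: pd.DataFrame | None = None   # per strain x condition IC50/Hill
    causal_markers: list[tuple[int, float]] = field(default_factory=list)
    kinship: np.ndarray | None = None
    cliques: list[list[str]] = field(default_factory=list)


def strain_frame(strains: list[StrainRecord]) -> pd.DataFrame:
    """Strain metadata as a DataFrame (the on-disk metadata table)."""
    return pd.DataFrame(
        [
            {
                "strain_id": s.strain_id, "category": s.category,
                "subcategory": s.subcategory, "geography": s.geography,
                "ploidy": s.ploidy, "bin_group": s.bin_group or "",
            }
            for s in strains
        ]
    )


# ---------------------------------------------------------------------------
# strains
# ---------------------------------------------------------------------------

def gen_strains(n: int, seed: int) -> list[StrainRecord]:
    """Generate ``n`` strain records covering all four categories.

    Category counts follow the emulated collection's 17:13:4:2 proportions
    (largest-remainder allocation with at least one strain per category).
    Bioethanol strains are placed in Brazil and share a bin group, so group
    tests can collapse them to one pseudo-observation.
    """
    if n < 4:
        raise ValueError("need n >= 4 to cover all four categories")
    rng = np.random.default_rng(seed)
    cats = list(CATEGORY_WEIGHTS)
    ideal = np.array([CATEGORY_WEIGHTS[c] * n for c in cats])
    counts = np.maximum(np.floor(ideal).astype(int), 1)
    while counts.sum() < n:  # largest remainder
        counts[int(np.argmax(ideal - counts))] += 1
    while counts.sum() > n:
        over = np.where(counts > 1)[0]
        counts[over[int(np.argmin((ideal - counts)[over]))]] -= 1

    records: list[StrainRecord] = []
    idx = itertools.count(1)
    for cat, cnt in zip(cats, counts):
        subcats = CATEGORY_SUBCATS[cat]
        for j in range(cnt):
            sub = subcats[j % len(subcats)]
            if sub == "bioethanol":
                geo = "Brazil"
            else:
                geo = str(rng.choice(GEOGRAPHIES))
            ploidy = 1 if sub == "lab" and j % 2 == 0 else int(rng.choice([1, 2], p=[0.2, 0.8]))
            records.append(
                StrainRecord(
                    strain_id=f"S{next(idx):03d}", category=cat, subcategory=sub,
                    geography=geo, ploidy=ploidy,
                )
            )
    bio = [r for r in records if r.subcategory == "bioethanol"]
    if len(bio) >= 2:
        for r in bio:
            r.bin_group = "brazil_bioethanol"
    return records


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def logistic_curve(
    t: np.ndarray, mu: float, lag: float, amp: float, baseline: float, y0: float
) -> np.ndarray:
    """Lagged logistic trajectory.

    Flat at ``baseline + y0`` (inoculum above blank) until ``lag``, then a
    logistic rise continuing from y0 with maximum specific rate ``mu`` toward
    carrying amplitude ``amp``:  y(t) = baseline + amp / (1 + (amp/y0 - 1)
    exp(-mu (t - lag))).  Closed form, continuous at ``lag``.
    """
    t = np.asarray(t, dtype=float)
    if amp <= y0:
        return np.full_like(t, baseline + y0)
    ratio = amp / y0 - 1.0
    growth = amp / (1.0 + ratio * np.exp(-mu * np.clip(t - lag, 0.0, None)))
    return baseline + np.where(t <= lag, y0, growth)


def true_t_half(mu: float, lag: float, amp: float, y0: float) -> float:
    """Time at which the curve reaches half its amplitude above blank."""
    return lag + np.log(amp / y0 - 1.0) / mu


def dose_factor(level: float, ic50: float, hill: float) -> float:
    """Hill-type retention factor in (0, 1]; level 0 -> 1 (no inhibition)."""
    if level <= 0:
        return 1.0
    return 1.0 / (1.0 + (level / ic50) ** hill)


def gen_growth_curves(
    strains: list[StrainRecord],
    n_conditions: int = 13,
    levels_per_condition: int | list[int] | None = None,
    n_replicates: int = 2,
    noise_sd: float = 0.01,
    seed: int = 0,
    t_max_h: float = 66.0,
    dt_h: float = 0.5,
    blank_threshold: float = 0.1,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate growth curves under increasing inhibitory levels.

    Per strain, baseline parameters (μ, λ, A) are drawn once; per condition a
    strain-specific IC50 and Hill slope drive a dose-response that degrades
    μ and A and inflates λ as the level index rises.  Amplitudes that fall
    below ``blank_threshold`` produce flat no-growth wells.  Levels per
    condition default to a draw in 4..7.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    conditions = [f"C{j + 1:02d}" for j in range(n_conditions)]
    if levels_per_condition is None:
        levels = rng.integers(4, 8, size=n_conditions).tolist()
    elif isinstance(levels_per_condition, int):
        levels = [levels_per_condition] * n_conditions
    else:
        levels = list(levels_per_condition)
        if len(levels) != n_conditions:
            raise ValueError("one level count per condition required")
    if any(l < 4 or l > 7 for l in levels):
        raise ValueError("levels per condition must be in 4..7")

    sp_rows, dr_rows = [], []
    for s in strains:
        sp_rows.append(
            {
                "strain_id": s.strain_id,
                "mu0": rng.uniform(0.25, 0.55),
                "lag0": rng.uniform(2.0, 6.0),
                "amp0": rng.uniform(0.8, 1.2),
                "baseline": rng.uniform(0.05, 0.10),
            }
        )
        for cond, n_lev in zip(conditions, levels):
            dr_rows.append(
                {
                    "strain_id": s.strain_id, "condition_id": cond,
                    "ic50": rng.uniform(1.5, n_lev + 1.0),
                    "hill": rng.uniform(1.5, 3.0),
                }
            )
    strain_params = pd.DataFrame(sp_rows).set_index("strain_id")
    dose_response = pd.DataFrame(dr_rows).set_index(["strain_id", "condition_id"])

    t = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    recs = []
    for s in strains:
        p = strain_params.loc[s.strain_id]
        y0 = 0.005 * p["amp0"]
        for cond, n_lev in zip(conditions, levels):
            d = dose_response.loc[(s.strain_id, cond)]
            for lev in range(n_lev):
                f = dose_factor(lev, d["ic50"], d["hill"])
                amp = p["amp0"] * f
                mu = p["mu0"] * f
                lag = p["lag0"] / f
                for rep in range(n_replicates):
                    if amp < blank_threshold or lag >= t_max_h:
                        clean = np.full_like(t, p["baseline"] + y0)
                    else:
                        clean = logistic_curve(t, mu, lag, amp, p["baseline"], y0)
                    sig = clean
                    if noise_sd > 0:
                        sig = np.clip(clean + rng.normal(0, noise_sd, t.size), 0, None)
                    recs.append(
                        pd.DataFrame(
                            {
                                "strain": s.strain_id, "condition": cond,
                                "level": lev, "replicate": rep,
                                "time_h": t, "signal": sig,
                            }
                        )
                    )
    frame = pd.concat(recs, ignore_index=True)
    truth = TruthSet(strain_params=strain_params.reset_index(),
                     dose_response=dose_response.reset_index())
    return frame, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def gen_genotypes(
    strains: list[StrainRecord] | int,
    n_markers: int,
    n_populations: int = 3,
    fst_like: float = 0.2,
    causal: list[tuple[int, float]] | None = None,
    sigma_g2: float = 1.0,
    sigma_e2: float = 1.0,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, TruthSet]:
    """Balding-Nichols structured genotypes plus a kinship-shaped phenotype.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_like``.
    Dosages are Binomial(2, p_pop).  The phenotype is the sum of planted
    marker effects (per dosage unit), a polygenic term ~ MVN(0, sigma_g2 K)
    with K the realized genomic relationship matrix, and iid noise.
    Returns (genotypes, phenotype, truth with the kinship used).
    """
    causal = list(causal or [])
    if not 0 < fst_like < 1:
        raise ValueError("fst_like must be in (0,1)")
    if any(j >= n_markers for j, _ in causal):
        raise ValueError("causal marker index out of range")
    rng = np.random.default_rng(seed)
    if isinstance(strains, int):
        names = [f"S{i + 1:03d}" for i in range(strains)]
    else:
        names = [s.strain_id for s in strains]
    n = len(names)
    pops = np.arange(n) % n_populations
    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    a = p_anc * (1 - fst_like) / fst_like
    b = (1 - p_anc) * (1 - fst_like) / fst_like
    p_pop = rng.beta(a[None, :], b[None, :], size=(n_populations, n_markers))
    dos = rng.binomial(2, p_pop[pops, :]).astype(float).T  # markers x strains

    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    chroms = list(chrom_lengths)
    per = int(np.ceil(n_markers / len(chroms)))
    marker_rows = []
    for j in range(n_markers):
        c = chroms[j // per]
        pos = 100 + (j % per) * max(50, chrom_lengths[c] // (per + 1))
        marker_rows.append(
            {"chrom": c, "pos": int(pos), "ref": "A", "alt": "T", "kind": "snp"}
        )
    markers = pd.DataFrame(marker_rows)

    gm = GenotypeMatrix(markers=markers, dosages=dos, strains=names)

    # polygenic term shaped by the realized GRM
    from .genotypes import kinship as _kinship

    K = _kinship(gm).values
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    g = np.sqrt(sigma_g2) * L @ rng.standard_normal(n)
    e = np.sqrt(sigma_e2) * rng.standard_normal(n)
    y = g + e
    for j, eff in causal:
        y = y + eff * dos[j]
    truth = TruthSet(causal_markers=causal, kinship=K)
    return gm, y, truth


# ---------------------------------------------------------------------------
# CNV segments and genes
# ---------------------------------------------------------------------------

def gen_cnv(
    strains: list[StrainRecord],
    chrom_lengths: dict[str, int] | None = None,
    n_events_per_strain: float = 4.0,
    shared_events: int = 4,
    shared_frac: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-strain CNV segments (chrom, start, end, copy_number, strain).

    Event positions are biased toward chromosome ends (subtelomeric-like,
    U-shaped Beta(0.5, 0.5) placement).  ``shared_events`` events are copied
    into a random ~``shared_frac`` subset of strains to create the overlap
    structure the CNV markers are built from.  Copy numbers: gain = ploidy+1
    or ploidy+2, loss = 1 (diploids), deletion = 0.
    """
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    ploidy = {s.strain_id: s.ploidy for s in strains}
    chroms = list(chrom_lengths)

    def draw_event() -> dict:
        c = str(rng.choice(chroms))
        length = int(rng.uniform(3_000, min(40_000, chrom_lengths[c] // 2)))
        start = int(rng.beta(0.5, 0.5) * (chrom_lengths[c] - length))
        kind = str(rng.choice(["gain", "loss", "deletion"], p=[0.5, 0.35, 0.15]))
        return {"chrom": c, "start": start, "end": start + length, "kind": kind}

    rows = []

    def add(ev: dict, strain_id: str) -> None:
        pl = ploidy[strain_id]
        if ev["kind"] == "gain":
            copy = pl + int(rng.integers(1, 3))
        elif ev["kind"] == "deletion":
            copy = 0
        else:
            copy = max(pl - 1, 1) if pl > 1 else 0
        rows.append(
            {"chrom": ev["chrom"], "start": ev["start"], "end": ev["end"],
             "copy_number": copy, "strain": strain_id}
        )

    for _ in range(shared_events):
        ev = draw_event()
        size = max(2, int(round(shared_frac * len(strains))))
        members = rng.choice([s.strain_id for s in strains], size=size, replace=False)
        for m in members:
            add(ev, str(m))
    for s in strains:
        for _ in range(rng.poisson(n_events_per_strain)):
            add(draw_event(), s.strain_id)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number", "strain"])
    return frame.sort_values(["chrom", "start", "end", "strain"]).reset_index(drop=True)


TF_SUPERFAMILIES = ("zipper", "HTH", "zinc finger", "other")
ORF_CLASSES = ("verified", "uncharacterized", "dubious")


def gen_genes(
    chrom_lengths: dict[str, int] | None = None,
    genes_per_chrom: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy gene catalogue: spans, strand, ORF class, TF superfamily labels."""
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    rows = []
    gid = itertools.count(1)
    for chrom, length in chrom_lengths.items():
        slots = np.linspace(0, length, genes_per_chrom + 1).astype(int)
        for a, b in zip(slots[:-1], slots[1:]):
            span = int(rng.uniform(0.3, 0.7) * (b - a))
            start = a + int(rng.uniform(0.1, 0.25) * (b - a))
            is_tf = rng.random() < 0.2
            rows.append(
                {
                    "gene_id": f"G{next(gid):04d}",
                    "chrom": chrom, "start": start, "end": start + max(span, 300),
                    "strand": str(rng.choice(["+", "-"])),
                    "orf_class": str(rng.choice(ORF_CLASSES, p=[0.7, 0.2, 0.1])),
                    "tf_superfamily": str(rng.choice(TF_SUPERFAMILIES)) if is_tf else "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def gen_network(
    n_nodes: int,
    edge_prob: float,
    planted_cliques: list[tuple[int, float]] | None = None,
    n_background_foreground: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], TruthSet]:
    """Erdős–Rényi background plus planted fully connected cliques.

    The foreground list contains the stated fraction of each planted clique
    plus ``n_background_foreground`` random non-clique nodes.  Edge scores
    are STRING-like confidences (background 400-800, clique edges 850-999).
    Returns (edge table, foreground list, truth with planted cliques).
    """
    planted_cliques = list(planted_cliques or [])
    if any(size > n_nodes for size, _ in planted_cliques):
        raise ValueError("clique size exceeds node count")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i + 1:04d}" for i in range(n_nodes)]
    edges: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu.size) < edge_prob
    for i, j in zip(iu[mask], ju[mask]):
        edges[(nodes[i], nodes[j])] = float(rng.uniform(400, 800))

    cliques: list[list[str]] = []
    foreground: list[str] = []
    cursor = 0
    for size, frac in planted_cliques:
        members = nodes[cursor : cursor + size]
        cursor += size
        cliques.append(members)
        for a, b in itertools.combinations(members, 2):
            edges[(a, b)] = float(rng.uniform(850, 999))
        n_fg = int(round(frac * size))
        foreground.extend(members[:n_fg])
    clique_nodes = {m for c in cliques for m in c}
    background_pool = [v for v in nodes if v not in clique_nodes]
    if n_background_foreground and background_pool:
        extra = rng.choice(
            background_pool,
            size=min(n_background_foreground, len(background_pool)),
            replace=False,
        )
        foreground.extend(str(x) for x in extra)
    edge_frame = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["node_a", "node_b", "score"],
    )
    return edge_frame, foreground, TruthSet(cliques=cliques)


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

DEFAULT_METABOLITE_GROUPS = (
    "proteinogenic amino acids", "fatty acid biosynthesis", "TCA cycle",
    "carboxylic acids", "aromatic compounds", "carboxylate degradation",
    "sugars", "nucleotides",
)


def gen_metabolome(
    strains: list[StrainRecord],
    n_metabolites: int = 79,
    group_map: dict[str, str] | None = None,
    group_effects: dict[tuple[str, str], float] | None = None,
    coupling: float = -0.6,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Log-normal metabolite abundances for intra/extracellular compartments.

    ``group_effects`` maps (group, strain subcategory) -> shift on the log
    scale applied to every member metabolite of that group for strains of
    that subcategory (e.g. higher fatty-acid biosynthesis in plant strains).
    The extracellular profile is coupled to the intracellular one with sign
    and strength ``coupling`` (negative = anti-correlated) plus noise.
    Returns ({"intra": df, "extra": df} with metabolites x strains,
    group_map).
    """
    rng = np.random.default_rng(seed)
    if group_map is None:
        mets = [f"M{i + 1:03d}" for i in range(n_metabolites)]
        group_map = {
            m: DEFAULT_METABOLITE_GROUPS[i % len(DEFAULT_METABOLITE_GROUPS)]
            for i, m in enumerate(mets)
        }
    else:
        mets = list(group_map)
        if len(mets) != n_metabolites:
            raise ValueError("group_map size must match n_metabolites")
    if any(not g for g in group_map.values()):
        raise ValueError("every metabolite needs a group")
    group_effects = dict(group_effects or {})
    names = [s.strain_id for s in strains]
    subcat = {s.strain_id: s.subcategory for s in strains}

    base = rng.uniform(2.0, 6.0, size=n_metabolites)
    log_intra = base[:, None] + rng.normal(0, noise_sd, size=(n_metabolites, len(names)))
    for i, m in enumerate(mets):
        for j, s in enumerate(names):
            eff = group_effects.get((group_map[m], subcat[s]), 0.0)
            log_intra[i, j] += eff
    centered = log_intra - log_intra.mean(axis=1, keepdims=True)
    log_extra = (
        base[:, None]
        + coupling * centered
        + rng.normal(0, noise_sd * max(1e-12, 1 - abs(coupling)), size=centered.shape)
    )
    intra = pd.DataFrame(np.power(10.0, log_intra), index=mets, columns=names)
    extra = pd.DataFrame(np.power(10.0, log_extra), index=mets, columns=names)
    return {"intra": intra, "extra": extra}, dict(group_map)
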