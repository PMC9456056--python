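"""Synthetic multiplexed CITE-seq study generator with known ground truth.

Emulates the study design the pipeline targets: subjects hash-tagged four
per plate, a ~49-antibody surface panel, a targeted transcript panel, and
condition-dependent cell-population structure.  Every downstream stage has a
recoverable target:

* cells belong to latent clusters spanning major lineages (B, monocyte,
  CD8 T, and several CD4 T memory subsets);
* each antibody is bimodal — a negative (background) and a positive normal
  component on the latent log2 scale, with per-cluster positivity — and UMI
  counts are negative binomial around 2**latent;
* transcript counts are negative binomial with per-cluster marker shifts and
  planted condition effects (log2 fold changes tied to CAD/DM/sex);
* per-subject cluster proportions follow logistic-scale shifts: a planted
  odds ratio multiplies the affected cluster's odds against the rest exactly;
* sample tags: the subject's own tag is high (Poisson), others ambient;
* doublets are sums of two singlets from distinct subjects on the same
  plate, so they carry two high tags; cross-lineage pairs are the
  "biological doublet" subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix


@dataclass(frozen=True)
class AntibodySpec:
    """One antibody: positive clusters plus component parameters (latent log2)."""

    name: str
    positive_in: frozenset[int]
    neg_mean: float = 1.0
    neg_sd: float = 0.5
    pos_mean: float = 6.0
    pos_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValueError("component sds must be positive")
        if self.pos_mean < self.neg_mean:
            raise ValueError("positive component mean below negative component mean")


CONDITIONS = ("CAD+", "CAD-", "DM+", "DM-", "male", "female")


def condition_mask(metadata: pd.DataFrame, condition: str) -> np.ndarray:
    """Boolean subject mask for a condition label (e.g. 'CAD+', 'DM-', 'female')."""
    if condition in ("CAD+", "CAD-"):
        return (metadata["cad_class"] == condition).to_numpy()
    if condition in ("DM+", "DM-"):
        return (metadata["dm"] == condition).to_numpy()
    if condition in ("male", "female"):
        return (metadata["sex"] == condition).to_numpy()
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


@dataclass
class SimulationDesign:
    n_subjects: int = 8
    cells_per_subject: int = 1500
    subjects_per_plate: int = 4
    n_clusters: int = 6
    cluster_base_proportions: tuple[float, ...] = (0.15, 0.15, 0.15, 0.25, 0.20, 0.10)
    cluster_major_types: tuple[str, ...] = ("B", "Monocyte", "CD8T", "CD4T", "CD4T", "CD4T")
    planted_abundance_effects: tuple[tuple[int, str, float], ...] = ()
    antibody_panel: tuple[AntibodySpec, ...] = ()
    n_genes: int = 200
    gene_names: tuple[str, ...] = ()
    gene_base_log2: tuple[float, ...] = ()
    cluster_gene_shifts: tuple[tuple[int, str, float], ...] = ()  # (cluster, gene, shift)
    planted_de_effects: tuple[tuple[str, str, float], ...] = ()  # (gene, condition, log2fc)
    doublet_rate: float = 0.05
    nb_dispersion_adt: float = 0.5
    nb_dispersion_gene: float = 0.2
    subject_logit_sd: float = 0.2
    tag_high_mean: float = 60.0
    tag_ambient_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_base_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_base_proportions must sum to 1")
        if len(self.cluster_base_proportions) != self.n_clusters:
            raise ValueError("proportions length must equal n_clusters")
        if len(self.cluster_major_types) != self.n_clusters:
            raise ValueError("cluster_major_types length must equal n_clusters")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must lie in [0, 0.5)")
        for clust, cond, orat in self.planted_abundance_effects:
            if not 0 <= clust < self.n_clusters:
                raise ValueError(f"abundance effect on unknown cluster {clust}")
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if orat <= 0:
                raise ValueError("odds_ratio must be > 0")
        if self.nb_dispersion_adt <= 0 or self.nb_dispersion_gene <= 0:
            raise ValueError("NB dispersions must be positive")
        if self.gene_names and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        names = set(self.gene_names)
        for gene, cond, _ in self.planted_de_effects:
            if names and gene not in names:
                raise ValueError(f"planted effect on unknown gene {gene!r}")
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        if len(self.planted_de_effects) > self.n_genes:
            raise ValueError("more planted effects than genes")


@dataclass
class GroundTruth:
    """Per-cell truth plus the generating parameters downstream stages target."""

    cells: pd.DataFrame  # index barcode: true_cluster, true_subject, true_major,
    #                      is_doublet, cross_lineage
    antibody_thresholds: pd.DataFrame  # antibody x cluster latent Bayes midpoints
    gene_effects: pd.DataFrame  # gene, condition, log2fc
    subject_cluster_props: pd.DataFrame  # subject x cluster expected proportions


def default_design(**overrides) -> SimulationDesign:
    """The default study design: 8 subjects crossing sex x CAD x DM.

    Six clusters (B, monocytes, CD8 T, CD4 central memory, CD4 effector
    memory, CCR2+ CD4 effector memory); the CCR2+ Em cluster is depleted in
    CAD+ (odds ratio 0.5).  Planted transcript effects: TCF7 up in both CAD+
    and DM+, GNAI2 up in CAD+, LAIR2 up in DM+, IFITM3 up in females, IL32
    up in DM- subjects; all at log2FC 1.0.
    """
    # gating lineage markers are bright (high positive mean, ~500 UMIs), as
    # abundant surface lineage antigens are in real panels; phenotype markers
    # sit at a more modest ~60 UMIs
    lineage = [
        AntibodySpec("CD3", frozenset({2, 3, 4, 5}), pos_mean=9.0),
        AntibodySpec("CD4", frozenset({3, 4, 5}), pos_mean=9.0),
        AntibodySpec("CD8", frozenset({2}), pos_mean=9.0),
        AntibodySpec("CD19", frozenset({0}), pos_mean=9.0),
        AntibodySpec("CD14", frozenset({1}), pos_mean=9.0),
        AntibodySpec("CD16", frozenset({1}), pos_mean=9.0),
        AntibodySpec("CD33", frozenset({1})),
        AntibodySpec("CD45RA", frozenset({0, 2})),
        AntibodySpec("CD197", frozenset({2, 3})),
        AntibodySpec("CCR2", frozenset({1, 5})),
    ]
    rng = np.random.default_rng(12345)  # design-construction rng, fixed
    fillers = []
    for i in range(len(lineage) + 1, 50):
        pos = frozenset(np.flatnonzero(rng.random(6) < 0.4).tolist())
        fillers.append(AntibodySpec(f"AB{i:02d}", pos))
    planted = ["TCF7", "GNAI2", "IFITM3", "LAIR2", "IL32"]
    n_genes = 200
    gene_names = tuple(planted + [f"G{i:03d}" for i in range(len(planted) + 1, n_genes + 1)])
    base = rng.uniform(-1.0, 3.0, size=n_genes)
    base[: len(planted)] = 2.5  # planted genes at a comfortably detectable depth
    # eight cluster-marker genes per cluster drawn from the filler genes
    marker_pool = rng.choice(np.arange(len(planted), n_genes), size=6 * 8, replace=False)
    shifts = tuple(
        (k, gene_names[g], 2.0)
        for k, block in enumerate(marker_pool.reshape(6, 8))
        for g in block
    )
    design = SimulationDesign(
        planted_abundance_effects=(((5, "CAD+", 0.5),)),
        antibody_panel=tuple(lineage + fillers),
        n_genes=n_genes,
        gene_names=gene_names,
        gene_base_log2=tuple(base),
        cluster_gene_shifts=shifts,
        planted_de_effects=(
            ("TCF7", "CAD+", 1.0),
            ("TCF7", "DM+", 1.0),
            ("GNAI2", "CAD+", 1.0),
            ("LAIR2", "DM+", 1.0),
            ("IFITM3", "female", 1.0),
            ("IL32", "DM-", 1.0),
        ),
    )
    if overrides:
        from dataclasses import replace

        design = replace(design, **overrides)
    return design


def simulate_metadata(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table crossing sex x CAD x DM (cycled beyond 8 subjects)."""
    rows = []
    for i in range(design.n_subjects):
        sex = "male" if (i >> 0) % 2 == 0 else "female"
        cad = "CAD+" if (i >> 1) % 2 == 0 else "CAD-"
        dm = "DM+" if (i >> 2) % 2 == 0 else "DM-"
        gensini = rng.uniform(35, 100) if cad == "CAD+" else rng.uniform(0, 5.5)
        rows.append(
            {
                "subject_id": f"S{i + 1:02d}",
                "sex": sex,
                "dm": dm,
                "statin": "yes",
                "gensini_score": round(float(gensini), 1),
                "cad_class": cad,
                "plate_id": f"P{i // design.subjects_per_plate + 1}",
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def subject_cluster_proportions(
    design: SimulationDesign, metadata: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-subject cluster proportions with planted logistic-scale shifts.

    Multiplying one cluster's softmax weight by the odds ratio scales its
    odds against all other clusters by exactly that factor; subject-level
    biological variability enters as N(0, subject_logit_sd) logit noise.
    """
    base = np.log(np.asarray(design.cluster_base_proportions))
    logits = np.tile(base, (design.n_subjects, 1))
    logits += rng.normal(0.0, design.subject_logit_sd, size=logits.shape)
    for clust, cond, orat in design.planted_abundance_effects:
        mask = condition_mask(metadata, cond)
        logits[mask, clust] += np.log(orat)
    props = np.exp(logits)
    props /= props.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=metadata.index, columns=range(design.n_clusters))


def simulate_cluster_counts(
    design: SimulationDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject x cluster cell counts only (no count matrices).

    The cheap path through the same generative model, for composition
    analyses; returns (counts frame, metadata).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    meta = simulate_metadata(design, rng)
    props = subject_cluster_proportions(design, meta, rng)
    counts = np.vstack(
        [rng.multinomial(design.cells_per_subject, p) for p in props.to_numpy()]
    )
    return pd.DataFrame(counts, index=meta.index, columns=props.columns), meta


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (size r = 1/dispersion)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_study(
    design: SimulationDesign, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate (antibody, gene, tag) count matrices, metadata, and truth."""
    if not design.antibody_panel:
        raise ValueError("design has an empty antibody panel")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    meta = simulate_metadata(design, rng)
    props = subject_cluster_proportions(design, meta, rng)
    n_total = design.n_subjects * design.cells_per_subject
    n_doublets = int(round(design.doublet_rate * n_total))
    n_singlets = n_total - n_doublets
    if n_doublets and design.n_subjects < 2:
        raise ValueError("doublets need at least two subjects")

    # component cells: singlets first, then 2*n_doublets doublet partners
    subj_pool = rng.permutation(np.repeat(np.arange(design.n_subjects), design.cells_per_subject))
    subj_singlet = subj_pool[:n_singlets]
    plate_of = np.arange(design.n_subjects) // design.subjects_per_plate
    partner_a = np.empty(n_doublets, dtype=int)
    partner_b = np.empty(n_doublets, dtype=int)
    for d in range(n_doublets):
        a = int(rng.integers(design.n_subjects))
        mates = np.flatnonzero((plate_of == plate_of[a]) & (np.arange(design.n_subjects) != a))
        if len(mates) == 0:
            mates = np.flatnonzero(np.arange(design.n_subjects) != a)
        partner_a[d] = a
        partner_b[d] = int(rng.choice(mates))
    comp_subjects = np.concatenate([subj_singlet, partner_a, partner_b])
    p_matrix = props.to_numpy()
    # vectorized categorical draw per component via CDF inversion
    cdf = np.cumsum(p_matrix, axis=1)
    u = rng.random(len(comp_subjects))
    comp_clusters = (u[:, None] > cdf[comp_subjects]).sum(axis=1)

    # antibody counts
    panel = design.antibody_panel
    n_ab = len(panel)
    pos_ind = np.zeros((design.n_clusters, n_ab), dtype=bool)
    mu_tab = np.zeros((2, n_ab))
    sd_tab = np.zeros((2, n_ab))
    for j, ab in enumerate(panel):
        pos_ind[list(ab.positive_in), j] = True
        mu_tab[:, j] = (ab.neg_mean, ab.pos_mean)
        sd_tab[:, j] = (ab.neg_sd, ab.pos_sd)
    is_pos = pos_ind[comp_clusters]
    latent = rng.normal(np.where(is_pos, mu_tab[1], mu_tab[0]),
                        np.where(is_pos, sd_tab[1], sd_tab[0]))
    adt_comp = _nb(rng, np.exp2(latent), design.nb_dispersion_adt)

    # gene counts
    gene_names = (
        np.asarray(design.gene_names, dtype=object)
        if design.gene_names
        else np.asarray([f"G{i:03d}" for i in range(1, design.n_genes + 1)], dtype=object)
    )
    base = (
        np.asarray(design.gene_base_log2, dtype=float)
        if design.gene_base_log2
        else np.full(design.n_genes, 1.5)
    )
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    clust_shift = np.zeros((design.n_clusters, design.n_genes))
    for k, gene, shift in design.cluster_gene_shifts:
        clust_shift[k, gene_idx[gene]] += shift
    cond_shift = np.zeros((design.n_subjects, design.n_genes))
    for gene, cond, lfc in design.planted_de_effects:
        cond_shift[condition_mask(meta, cond), gene_idx[gene]] += lfc
    log2_mu = base[None, :] + clust_shift[comp_clusters] + cond_shift[comp_subjects]
    gene_comp = _nb(rng, np.exp2(log2_mu), design.nb_dispersion_gene)

    # tag counts (one tag per subject)
    tag_comp = rng.poisson(design.tag_ambient_mean,
                           size=(len(comp_subjects), design.n_subjects))
    tag_comp[np.arange(len(comp_subjects)), comp_subjects] += rng.poisson(
        design.tag_high_mean, size=len(comp_subjects))

    # assemble doublets by summing partner components
    sl = slice(0, n_singlets)
    pa = slice(n_singlets, n_singlets + n_doublets)
    pb = slice(n_singlets + n_doublets, n_singlets + 2 * n_doublets)
    adt = np.vstack([adt_comp[sl], adt_comp[pa] + adt_comp[pb]])
    genes = np.vstack([gene_comp[sl], gene_comp[pa] + gene_comp[pb]])
    tags = np.vstack([tag_comp[sl], tag_comp[pa] + tag_comp[pb]])

    majors = np.asarray(design.cluster_major_types, dtype=object)
    cl_a, cl_b = comp_clusters[pa], comp_clusters[pb]
    cross = majors[cl_a] != majors[cl_b]
    truth = pd.DataFrame(
        {
            "true_cluster": pd.array(
                np.concatenate([comp_clusters[sl], np.full(n_doublets, -1)]), dtype="Int64"
            ),
            "true_subject": pd.array(
                [meta.index[s] for s in comp_subjects[sl]] + [pd.NA] * n_doublets,
                dtype="string",
            ),
            "true_major": pd.array(
                list(majors[comp_clusters[sl]]) + [pd.NA] * n_doublets, dtype="string"
            ),
            "is_doublet": np.concatenate(
                [np.zeros(n_singlets, bool), np.ones(n_doublets, bool)]
            ),
            "cross_lineage": np.concatenate([np.zeros(n_singlets, bool), cross]),
        }
    )
    truth.loc[truth["true_cluster"] == -1, "true_cluster"] = pd.NA

    order = rng.permutation(n_total)
    barcodes = np.asarray([f"cell{i + 1:06d}" for i in range(n_total)], dtype=object)
    truth = truth.iloc[order].set_index(pd.Index(barcodes, name="barcode"))
    ab_names = np.asarray([ab.name for ab in panel], dtype=object)
    adt_mat = CountMatrix(barcodes, ab_names, adt[order], "antibody")
    gene_mat = CountMatrix(barcodes, gene_names, genes[order], "gene")
    tag_mat = CountMatrix(barcodes, meta.index.to_numpy(dtype=object), tags[order], "tag")

    thr = pd.DataFrame(
        {k: [(ab.neg_mean + ab.pos_mean) / 2 for ab in panel] for k in range(design.n_clusters)},
        index=ab_names,
    )
    effects = pd.DataFrame(design.planted_de_effects, columns=["gene", "condition", "log2fc"])
    gt = GroundTruth(
        cells=truth,
        antibody_thresholds=thr,
        gene_effects=effects,
        subject_cluster_props=props,
    )
    return adt_mat, gene_mat, tag_mat, meta, gt
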