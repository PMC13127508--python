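"""Synthetic snRNA-seq-like and tumor scRNA-seq-like data with planted truth.

The exocrine generator emulates multi-donor pancreas nuclei across three
contexts (neonatal / adult / chronic pancreatitis): seven exocrine
subtypes driven by marker-gene panels, a sparse TF transcript whose latent
activity nonetheless structures its regulon targets, technical covariates
(library size, %mito, %ribo, ambient contamination), donor batch shifts,
and an acinar-to-ductal lineage with a progression expression gradient.
Counts are negative-binomial with a multiplicative library-size factor and
an expression-dependent extra dropout, the simplest mechanism reproducing
single-nucleus overdispersion and detection sparsity.

The tumor generator emulates 15 samples of tumor cells mixing along a
Classical-Basal signature continuum, with the true family labels derived
from the latent classical fraction by the explicit thresholds.

Focused generators (per-gene hurdle effects, module scores, clone qPCR
expression) plant exactly the parameters the corresponding estimators are
meant to recover.  All randomness flows from a single integer seed per
call; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix, GeneSetCollection, Regulon, log_normalize, make_annotated

SUBTYPES = (
    "Acinar",
    "Acinar_REG+",
    "Acinar-stress",
    "Ductal",
    "Ductal-CFTRhi",
    "Ductal-MUC5B",
    "Ductal-injury",
)

DEFAULT_PROPORTIONS = {
    "Acinar": 0.30,
    "Acinar_REG+": 0.10,
    "Acinar-stress": 0.10,
    "Ductal": 0.20,
    "Ductal-CFTRhi": 0.12,
    "Ductal-MUC5B": 0.10,
    "Ductal-injury": 0.08,
}

DEFAULT_LINEAGES = (
    ("Acinar", "Acinar-stress", "Ductal", "Ductal-CFTRhi"),
    ("Acinar", "Acinar-stress", "Ductal", "Ductal-MUC5B"),
    ("Acinar", "Acinar-stress", "Ductal", "Ductal-injury"),
    ("Acinar", "Acinar_REG+"),
)


class ConfigError(ValueError):
    pass


@dataclass
class ExocrineSimConfig:
    n_cells: int = 2000
    n_genes: int = 1500
    contexts: tuple[str, ...] = ("neonatal", "adult", "CP")
    donors_per_context: int = 2
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    tf_name: str = "TF1"
    tf_activity_sd: float = 1.0
    regulon_size: int = 100
    regulon_effect: float = 0.5
    frac_repressed: float = 0.25
    dropout_logit_slope: float = 1.0
    dropout_logit_offset: float = 2.0
    nb_dispersion: float = 0.5
    batch_effect_sd: float = 0.1
    marker_genes_per_subtype: int = 20
    marker_boost: float = 1.5
    n_family_genes: int = 15
    family_boost: float = 1.5
    n_progression_genes: int = 30
    progression_slope: float = 0.4
    lineage_spec: tuple[tuple[str, ...], ...] = DEFAULT_LINEAGES
    library_log_sd: float = 0.3
    baseline_log_mean: float = -1.2
    baseline_log_sd: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("subtype proportions must sum to 1")
        if self.regulon_size < 5:
            raise ConfigError("regulon_size below the minimum regulon size of 5")
        for n, label in [
            (self.n_cells, "n_cells"),
            (self.n_genes, "n_genes"),
            (self.donors_per_context, "donors_per_context"),
            (self.marker_genes_per_subtype, "marker_genes_per_subtype"),
        ]:
            if n < 1:
                raise ConfigError(f"{label} must be >= 1")
        needed = (
            len(self.subtype_proportions) * self.marker_genes_per_subtype
            + 2 * self.n_family_genes
            + self.n_progression_genes
            + self.regulon_size
            + 1
        )
        if self.n_genes < needed:
            raise ConfigError(f"n_genes={self.n_genes} too small for layout (need {needed})")


@dataclass
class SimTruth:
    """Planted ground truth aligned to the emitted matrix's cell ids."""

    activity_true: pd.Series | None = None
    subtype_true: pd.Series | None = None
    pseudotime_true: pd.Series | None = None
    module_effects: dict[str, float] = field(default_factory=dict)
    module_sets: dict[str, list[str]] = field(default_factory=dict)
    gene_effects: pd.DataFrame | None = None  # logOR_det_true, beta_cont_true
    p_classical_true: pd.Series | None = None
    family_true: pd.Series | None = None


def _stage_depth(lineage_spec) -> dict[str, int]:
    depth: dict[str, int] = {}
    for path in lineage_spec:
        for k, subtype in enumerate(path):
            depth.setdefault(subtype, k)
    return depth


def generate_regulon(
    tf: str,
    n_targets: int,
    frac_repressed: float,
    seed: int,
    gene_universe: list[str],
) -> Regulon:
    """Random regulon: targets without replacement, round(frac) repressed, weight 1."""
    if n_targets < 5:
        raise ConfigError("n_targets below the minimum regulon size of 5")
    if n_targets > len(gene_universe):
        raise ConfigError("n_targets exceeds the gene universe")
    rng = np.random.default_rng(seed)
    targets = rng.choice(np.asarray(gene_universe, dtype=object), size=n_targets, replace=False)
    modes = np.ones(n_targets, dtype=int)
    n_rep = int(round(frac_repressed * n_targets))
    if n_rep:
        rep_idx = rng.choice(n_targets, size=n_rep, replace=False)
        modes[rep_idx] = -1
    edges = pd.DataFrame(
        {"tf": tf, "target": targets, "mode": modes, "weight": 1.0}
    )
    reg = Regulon(edges)
    reg.validate()
    return reg


def _technical_covariates(rng, n_cells, lib_log):
    """%mito / %ribo / contamination with mild library-size correlation."""
    z_lib = (lib_log - lib_log.mean()) / max(lib_log.std(), 1e-12)
    pct_mito = np.clip(rng.normal(5.0, 2.0, n_cells) - 1.0 * z_lib, 0.05, 60.0)
    pct_ribo = np.clip(rng.normal(15.0, 5.0, n_cells) - 2.0 * z_lib, 0.1, 80.0)
    contamination = np.clip(rng.beta(2.0, 10.0, n_cells) + 0.02 * z_lib, 0.0, 1.0)
    return pct_mito, pct_ribo, contamination


def _nb_sample(rng, mu, dispersion):
    """NB draws with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_exocrine_dataset(
    cfg: ExocrineSimConfig,
) -> tuple[AnnotatedMatrix, SimTruth, Regulon, GeneSetCollection]:
    """Simulate the exocrine snRNA-seq-like dataset with planted truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    subtypes = list(cfg.subtype_proportions)

    # --- gene layout --------------------------------------------------
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cursor = 0
    marker_sets: dict[str, list[str]] = {}
    for s in subtypes:
        marker_sets[s] = genes[cursor : cursor + cfg.marker_genes_per_subtype]
        cursor += cfg.marker_genes_per_subtype
    acinar_program = genes[cursor : cursor + cfg.n_family_genes]
    cursor += cfg.n_family_genes
    ductal_program = genes[cursor : cursor + cfg.n_family_genes]
    cursor += cfg.n_family_genes
    progression_genes = genes[cursor : cursor + cfg.n_progression_genes]
    cursor += cfg.n_progression_genes
    tf_gene = cfg.tf_name
    genes[cursor] = tf_gene
    cursor += 1
    target_pool = genes[cursor:]

    regulon = generate_regulon(
        cfg.tf_name, cfg.regulon_size, cfg.frac_repressed,
        seed=int(rng.integers(2**31)), gene_universe=target_pool,
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    mode_vec = np.zeros(cfg.n_genes)
    for _, row in regulon.edges.iterrows():
        mode_vec[gene_pos[row["target"]]] = row["mode"]

    # --- cells --------------------------------------------------------
    cell_ids = [f"cell_{i:05d}" for i in range(cfg.n_cells)]
    props = np.array([cfg.subtype_proportions[s] for s in subtypes])
    subtype_idx = rng.choice(len(subtypes), size=cfg.n_cells, p=props)
    subtype_true = np.array(subtypes, dtype=object)[subtype_idx]

    depth = _stage_depth(cfg.lineage_spec)
    stage = np.array([depth.get(s, 0) for s in subtype_true], dtype=float)
    pseudotime_true = stage + rng.uniform(0.0, 1.0, cfg.n_cells)

    context = rng.choice(np.asarray(cfg.contexts, dtype=object), size=cfg.n_cells)
    donor_of = {
        c: [f"{c}_d{j + 1}" for j in range(cfg.donors_per_context)] for c in cfg.contexts
    }
    donor = np.array(
        [donor_of[c][rng.integers(cfg.donors_per_context)] for c in context], dtype=object
    )
    donors = sorted({d for ds in donor_of.values() for d in ds})
    donor_shift = {d: rng.normal(0.0, cfg.batch_effect_sd, cfg.n_genes) for d in donors}

    activity = rng.normal(0.0, cfg.tf_activity_sd, cfg.n_cells)
    lib_log = rng.normal(0.0, cfg.library_log_sd, cfg.n_cells)

    # --- expression model --------------------------------------------
    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    baseline[gene_pos[tf_gene]] = -3.2  # sparse TF transcript (detection < 10%)

    log_mu = np.tile(baseline, (cfg.n_cells, 1))
    for s in subtypes:
        cells = subtype_idx == subtypes.index(s)
        cols = [gene_pos[g] for g in marker_sets[s]]
        log_mu[np.ix_(cells, cols)] += cfg.marker_boost
    # shared family programs: acinar states express an acinar program,
    # ductal states a ductal core; the stress state is transitional,
    # expressing a reduced acinar dose plus a partial ductal dose
    acinar_dose = {"Acinar": 1.0, "Acinar_REG+": 1.0, "Acinar-stress": 0.8}
    ductal_dose = {
        "Ductal": 1.0,
        "Ductal-CFTRhi": 1.0,
        "Ductal-MUC5B": 1.0,
        "Ductal-injury": 1.0,
        "Acinar-stress": 0.5,
    }
    aci_cols = [gene_pos[g] for g in acinar_program]
    duc_cols = [gene_pos[g] for g in ductal_program]
    aci_vec = np.array([acinar_dose.get(s, 0.0) for s in subtype_true])
    duc_vec = np.array([ductal_dose.get(s, 0.0) for s in subtype_true])
    log_mu[:, aci_cols] += cfg.family_boost * aci_vec[:, None]
    log_mu[:, duc_cols] += cfg.family_boost * duc_vec[:, None]
    prog_cols = [gene_pos[g] for g in progression_genes]
    log_mu[:, prog_cols] += cfg.progression_slope * pseudotime_true[:, None]
    log_mu += cfg.regulon_effect * activity[:, None] * mode_vec[None, :]
    for d in donors:
        cells = donor == d
        log_mu[cells] += donor_shift[d][None, :]
    log_mu += lib_log[:, None]

    mu = np.exp(log_mu)
    counts = _nb_sample(rng, mu, cfg.nb_dispersion)
    if cfg.dropout_logit_slope > 0:
        keep_logit = cfg.dropout_logit_offset + cfg.dropout_logit_slope * np.log1p(mu)
        keep_p = 1.0 / (1.0 + np.exp(-keep_logit))
        counts = counts * (rng.uniform(size=counts.shape) < keep_p)
    counts = counts.astype(np.int64)

    # guard: no zero-total cells (resample minimal signal into empties)
    totals = counts.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    for c in empty:
        counts[c, rng.integers(cfg.n_genes)] = 1

    pct_mito, pct_ribo, contamination = _technical_covariates(rng, cfg.n_cells, lib_log)
    meta = pd.DataFrame(
        {
            "donor": donor,
            "context": context,
            "sample": donor,  # one sample per donor
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "contamination": contamination,
            "subtype": subtype_true,
            "cluster": subtype_true,  # planted cluster labels
        }
    )
    m = make_annotated(counts, cell_ids, genes, cell_meta=meta)
    m = log_normalize(m)

    # --- axis panels (two ductal-core-like axes map to one label) -----
    half = cfg.marker_genes_per_subtype // 2
    panels = GeneSetCollection(
        sets={
            "acinar": marker_sets["Acinar"],
            "acinar_reg": marker_sets["Acinar_REG+"],
            "acinar_stress": marker_sets["Acinar-stress"],
            "ductal_core_1": marker_sets["Ductal"][:half],
            "ductal_core_2": marker_sets["Ductal"][half:],
            "ductal_cftr": marker_sets["Ductal-CFTRhi"],
            "ductal_muc5b": marker_sets["Ductal-MUC5B"],
            "ductal_injury": marker_sets["Ductal-injury"],
        },
        kind="axis_panel",
    )
    panels.validate()

    activated = regulon.edges.loc[regulon.edges["mode"] == 1, "target"].tolist()
    repressed = regulon.edges.loc[regulon.edges["mode"] == -1, "target"].tolist()
    module_sets = {"tf_activated": activated[:20] or activated}
    module_effects = {"tf_activated": cfg.regulon_effect}
    if repressed:
        module_sets["tf_repressed"] = repressed[:20]
        module_effects["tf_repressed"] = -cfg.regulon_effect
    module_sets["progression"] = progression_genes
    module_effects["progression"] = 0.0
    module_sets["acinar_program"] = acinar_program
    module_effects["acinar_program"] = 0.0
    module_sets["ductal_core"] = ductal_program
    module_effects["ductal_core"] = 0.0

    idx = pd.Index(cell_ids, name="cell_id")
    truth = SimTruth(
        activity_true=pd.Series(activity, index=idx),
        subtype_true=pd.Series(subtype_true, index=idx),
        pseudotime_true=pd.Series(pseudotime_true, index=idx),
        module_effects=module_effects,
        module_sets=module_sets,
    )
    return m, truth, regulon, panels


# ----------------------------------------------------------------------
def default_tumor_signatures(n_genes_per_sig: int = 80) -> GeneSetCollection:
    """Disjoint synthetic stand-ins for the four published NMF signatures."""
    sets = {}
    cursor = 0
    for name in ("Sig1", "Sig2", "Sig6", "Sig10"):
        sets[name] = [f"G{cursor + i:05d}" for i in range(n_genes_per_sig)]
        cursor += n_genes_per_sig
    return GeneSetCollection(sets=sets, kind="nmf_signature")


def _draw_continuum(rng, spec, n: int) -> np.ndarray:
    if isinstance(spec, str):
        spec = (spec,)
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if kind == "degenerate":
        return np.full(n, float(spec[1]))
    if kind == "beta":
        return rng.beta(float(spec[1]), float(spec[2]), n)
    raise ConfigError(f"unknown continuum_mix spec {spec!r}")


def generate_tumor_dataset(
    n_cells: int = 3000,
    n_samples: int = 15,
    signature_sets: GeneSetCollection | None = None,
    continuum_mix="sample_anchored",
    seed: int = 0,
    n_genes: int = 800,
    signature_effect: float = 1.0,
    nb_dispersion: float = 0.5,
    sample_effect_sd: float = 0.1,
    library_log_sd: float = 0.3,
    baseline_log_mean: float = -0.7,
    activity_by_family: dict[str, float] | None = None,
) -> tuple[AnnotatedMatrix, SimTruth]:
    """Simulate tumor cells along the Classical-Basal continuum.

    Each cell draws a latent classical fraction from ``continuum_mix``;
    classical signature genes (Sig1, Sig6) scale with that fraction and
    basal genes (Sig2, Sig10) with its complement.  True families follow
    the thresholds applied to the latent fractions.

    The default ``"sample_anchored"`` continuum emulates a cohort in which
    each tumor sample is dominated by one family: each sample draws a
    classical/basal/intermediate anchor, and its cells scatter around that
    anchor along the continuum.  ``"uniform"``, ``("degenerate", x)`` and
    ``("beta", a, b)`` draw every cell's fraction i.i.d.
    """
    from .tumor import classify_family

    rng = np.random.default_rng(seed)
    if signature_sets is None:
        signature_sets = default_tumor_signatures()
    all_sig_genes: list[str] = []
    for name in ("Sig1", "Sig2", "Sig6", "Sig10"):
        if name not in signature_sets.sets:
            raise ConfigError(f"signature collection missing {name}")
        all_sig_genes.extend(signature_sets[name])
    if len(set(all_sig_genes)) != len(all_sig_genes):
        raise ConfigError("signature gene lists overlap")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    missing = [g for g in all_sig_genes if g not in set(genes)]
    if missing:
        raise ConfigError(f"signature genes outside the gene universe, e.g. {missing[:3]}")
    gene_pos = {g: i for i, g in enumerate(genes)}

    sample = np.array(
        [f"tumor_{rng.integers(n_samples) + 1:02d}" for _ in range(n_cells)], dtype=object
    )
    samples = sorted(set(sample))

    if continuum_mix == "sample_anchored":
        # per-sample anchors: classical-, basal-dominant and intermediate
        # tumors in roughly equal numbers; cells scatter around the anchor
        anchors = {}
        for i, s in enumerate(samples):
            kind = i % 3
            if kind == 0:
                anchors[s] = rng.beta(30.0, 4.0)
            elif kind == 1:
                anchors[s] = rng.beta(4.0, 30.0)
            else:
                anchors[s] = rng.beta(40.0, 40.0)
        kappa = 100.0
        centers = np.array([anchors[s] for s in sample])
        f_classical = rng.beta(kappa * centers, kappa * (1.0 - centers))
    else:
        f_classical = _draw_continuum(rng, continuum_mix, n_cells)
    p_basal = 1.0 - f_classical
    family_true = np.array(
        [classify_family(fc, fb) for fc, fb in zip(f_classical, p_basal)], dtype=object
    )
    sample_shift = {s: rng.normal(0.0, sample_effect_sd, n_genes) for s in samples}

    baseline = rng.normal(baseline_log_mean, 0.6, n_genes)
    lib_log = rng.normal(0.0, library_log_sd, n_cells)

    log_mu = np.tile(baseline, (n_cells, 1))
    for s in samples:
        cells = sample == s
        log_mu[cells] += sample_shift[s][None, :]
    log_mu += lib_log[:, None]
    mu = np.exp(log_mu)

    # signature genes follow a linear-rate model: the mean count scales
    # directly with the latent loading, so the per-cell score fractions
    # track the latent classical fraction instead of compressing to 0.5
    for name, latent in (
        ("Sig1", f_classical),
        ("Sig6", f_classical),
        ("Sig2", p_basal),
        ("Sig10", p_basal),
    ):
        cols = [gene_pos[g] for g in signature_sets[name]]
        scale = np.exp(lib_log)
        mu[:, cols] = (0.02 + signature_effect * latent)[:, None] * scale[:, None]

    counts = _nb_sample(rng, mu, nb_dispersion).astype(np.int64)
    totals = counts.sum(axis=1)
    for c in np.flatnonzero(totals == 0):
        counts[c, rng.integers(n_genes)] = 1

    pct_mito, pct_ribo, contamination = _technical_covariates(rng, n_cells, lib_log)
    meta = pd.DataFrame(
        {
            "donor": sample,
            "context": "tumor",
            "sample": sample,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "contamination": contamination,
            "cluster": family_true,
        }
    )
    cell_ids = [f"tcell_{i:05d}" for i in range(n_cells)]
    m = make_annotated(counts, cell_ids, genes, cell_meta=meta)
    m = log_normalize(m)

    idx = pd.Index(cell_ids, name="cell_id")
    truth = SimTruth(
        p_classical_true=pd.Series(f_classical, index=idx),
        family_true=pd.Series(family_true, index=idx),
    )
    if activity_by_family is not None:
        shift = np.array([activity_by_family.get(f, 0.0) for f in family_true])
        truth.activity_true = pd.Series(shift + rng.normal(0.0, 0.5, n_cells), index=idx)
    return m, truth


# ----------------------------------------------------------------------
def generate_hurdle_genes(
    n_cells: int = 2000,
    n_genes: int = 1,
    logOR_det: float = 0.0,
    beta_cont: float = 0.0,
    seed: int = 0,
    base_logit: float = 0.0,
    base_mean: float = 2.0,
    cont_sd: float = 0.5,
    n_donors: int = 4,
    donor_effect_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, SimTruth]:
    """Plant exact hurdle effects: detection log-odds and continuous slope.

    Detection is Bernoulli with logit = base_logit + logOR_det * activity
    + donor shift; detected expression is Gaussian around base_mean +
    beta_cont * activity + donor shift (floored just above zero so the
    detection indicator stays consistent).  Returns (expr matrix, activity,
    metadata with donor labels, truth).
    """
    rng = np.random.default_rng(seed)
    activity = rng.normal(0.0, 1.0, n_cells)
    donor = np.array([f"d{rng.integers(n_donors) + 1}" for _ in range(n_cells)], dtype=object)
    donors = sorted(set(donor))
    det_shift = {d: rng.normal(0.0, donor_effect_sd) for d in donors}
    cont_shift = {d: rng.normal(0.0, donor_effect_sd) for d in donors}
    det_off = np.array([det_shift[d] for d in donor])
    cont_off = np.array([cont_shift[d] for d in donor])

    expr = np.zeros((n_cells, n_genes))
    for j in range(n_genes):
        logit = base_logit + logOR_det * activity + det_off
        det = rng.uniform(size=n_cells) < 1.0 / (1.0 + np.exp(-logit))
        level = base_mean + beta_cont * activity + cont_off + rng.normal(0.0, cont_sd, n_cells)
        expr[:, j] = np.where(det, np.maximum(level, 0.01), 0.0)

    meta = pd.DataFrame({"donor": donor})
    truth = SimTruth(
        activity_true=pd.Series(activity),
        gene_effects=pd.DataFrame(
            {"logOR_det_true": [logOR_det] * n_genes, "beta_cont_true": [beta_cont] * n_genes}
        ),
    )
    return expr, activity, meta, truth


def simulate_module_scores(
    activity: np.ndarray,
    coefficient: float,
    noise_sd: float = 0.5,
    seed: int = 0,
    confounder: np.ndarray | None = None,
    confounder_effect: float = 0.0,
) -> np.ndarray:
    """Module scores = coefficient * activity (+ confounder effect) + noise."""
    rng = np.random.default_rng(seed)
    activity = np.asarray(activity, dtype=float)
    scores = coefficient * activity + rng.normal(0.0, noise_sd, len(activity))
    if confounder is not None:
        scores = scores + confounder_effect * np.asarray(confounder, dtype=float)
    return scores


def generate_clone_expression(
    n_clones: int = 12,
    reps: int = 3,
    dose_effect: float = -0.8,
    clone_sd: float = 0.2,
    resid_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Clone qPCR-style expression on the INT scale with a planted dose effect.

    Clones split evenly across genotype doses 0/1/2; each clone has its own
    random intercept and ``reps`` replicate measurements.
    """
    if n_clones < 3:
        raise ConfigError("need at least 3 clones (one per dose)")
    rng = np.random.default_rng(seed)
    doses = np.tile([0, 1, 2], n_clones // 3 + 1)[:n_clones]
    rows = []
    for i in range(n_clones):
        intercept = rng.normal(0.0, clone_sd)
        for _ in range(reps):
            rows.append(
                {
                    "clone": f"clone_{i + 1:02d}",
                    "dose": int(doses[i]),
                    "expression": dose_effect * doses[i]
                    + intercept
                    + rng.normal(0.0, resid_sd),
                }
            )
    return pd.DataFrame(rows)
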