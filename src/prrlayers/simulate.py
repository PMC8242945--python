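"""Synthetic LPS-challenge experiments with planted ground truth.

The generator emulates the design of a sponge LPS-challenge RNA-seq study:
two treatments (LPS injection vs artificial-seawater sham control), two
sampling timepoints (1 h and 6 h), and n biological replicates per
treatment, where each replicate is a clone pair — the same sponge individual
sampled at both timepoints within its treatment, with distinct individuals
per treatment. Dropout cells (e.g. one LPS replicate lost at 6 h) can be
listed explicitly, reproducing unbalanced designs such as 23 = 24 - 1
samples.

Expression has three planted layers:

* constitutive genes — a positive negative-binomial mean in every sample
  (baseline means log-normal with a floor so presence is recoverable from
  observed counts);
* individual-specific genes — each individual carries the gene or not
  (structural zeros are exact zeros); carriage is decided per individual, so
  both clones of a carrier express it regardless of timepoint;
* never-expressed genes — all-zero rows.

A subset of constitutive genes responds to LPS: their mean is multiplied by
2**(+-effect_log2fc) in the LPS samples of responder individuals only, with
per-gene responder penetrance controlling how many of the LPS individuals
respond. Direction is drawn once per gene, by default biased toward
down-regulation. Constitutive immune-flagged genes get a multiplicative
baseline boost so the immune-vs-other median comparison has a known truth.

Counts are negative binomial with variance mu + dispersion * mu**2, drawn
as a gamma-Poisson mixture; dispersion -> 0 degrades gracefully to Poisson.
All randomness derives from one seed through named substreams, so identical
(config, design) inputs give byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import domains as dom

TREATMENTS = ("LPS", "control")
TIMEPOINTS = ("t1h", "t6h")

_INNOCUOUS_DOMAINS = (
    # accessions that trigger no family rule on their own
    ("PF00069", "Pkinase"),
    ("PF00041", "fn3"),
    ("PF00008", "EGF"),
    ("PF12796", "Ank_2"),
    ("PF00084", "Sushi"),
    ("PF00047", "ig"),       # Ig without TIR
    ("PF13516", "LRR_6"),    # LRR without NACHT
    ("PF01825", "GPS"),      # GPS without 7TM
)

_DOMAIN_NAMES = {
    dom.TIR: "TIR",
    dom.IG_LIKE: "ig",
    dom.NACHT: "NACHT",
    dom.LRR: "LRR_6",
    dom.GPS: "GPS",
    dom.CTL: "Lectin_C",
    "PF00530": "SRCR",
    "PF15494": "SRCR_2",
    "PF00001": "7tm_1",
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults reproduce the study design this generator emulates: 6
    individuals per treatment, a 40/40/20 constitutive / individual-specific
    / never-expressed split, per-individual carriage probability 0.5 for
    individual-specific genes, 200 LPS-responsive genes with |log2FC| = 3
    and full responder penetrance, log-normal baseline means, NB dispersion
    0.2, 10% immune-flagged genes with a 1.35x constitutive-median boost.
    """

    n_individuals: int = 6
    n_genes: int = 20_000
    frac_constitutive: float = 0.40
    frac_individual_specific: float = 0.40
    frac_never_expressed: float = 0.20
    presence_prob: float = 0.5
    n_responsive: int = 200
    #: fraction of LPS individuals in which a responsive gene responds;
    #: a sequence is cycled across responsive genes (mixed penetrance)
    responder_penetrance: float | tuple = 1.0
    effect_log2fc: float = 3.0
    prob_down: float = 0.6
    mean_log_mu: float = 4.0
    sd_log_mu: float = 1.0
    constitutive_mu_floor: float = 20.0
    dispersion: float = 0.2
    frac_immune: float = 0.10
    immune_median_boost: float = 1.35
    length_mean_log: float = np.log(2000.0)
    length_sd_log: float = 0.6
    n_receptors_per_family: int = 25
    seed: int = 0
    # default design mirrors the emulated study: one LPS replicate lost at
    # 6 h, so 2 treatments x 2 timepoints x 6 individuals gives 23 samples
    dropout_samples: tuple = (("LPS06", "LPS", "t6h"),)

    def __post_init__(self) -> None:
        fracs = (
            self.frac_constitutive,
            self.frac_individual_specific,
            self.frac_never_expressed,
            self.presence_prob,
            *np.atleast_1d(self.responder_penetrance).tolist(),
            self.frac_immune,
            self.prob_down,
        )
        for f in fracs:
            if not np.isfinite(f) or not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        s = (
            self.frac_constitutive
            + self.frac_individual_specific
            + self.frac_never_expressed
        )
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"layer fractions sum to {s}, expected 1")
        if self.dispersion <= 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be positive and finite")
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive exceeds n_genes")
        for name in ("mean_log_mu", "sd_log_mu", "effect_log2fc",
                     "immune_median_boost", "constitutive_mu_floor"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Named, order-independent RNG substream of the global seed."""
    digest = np.frombuffer(label.encode(), dtype=np.uint8)
    return np.random.default_rng(
        np.random.SeedSequence([seed, *digest.tolist()])
    )


def simulate_design(
    n_individuals: int = 6,
    dropout_samples: Sequence[tuple[str, str, str]] = (),
) -> pd.DataFrame:
    """Build the clone-pair sample design table.

    Each treatment has its own pool of ``n_individuals`` individuals
    (``LPS01..`` and ``CTR01..``); every individual is sampled at both
    timepoints unless its (individual, treatment, timepoint) cell is listed
    in ``dropout_samples``. No individual appears in both treatments.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals per treatment")
    dropouts = {tuple(d) for d in dropout_samples}
    rows = []
    for treatment in TREATMENTS:
        prefix = "LPS" if treatment == "LPS" else "CTR"
        for i in range(1, n_individuals + 1):
            ind = f"{prefix}{i:02d}"
            for tp in TIMEPOINTS:
                if (ind, treatment, tp) in dropouts:
                    continue
                rows.append(
                    {
                        "sample_id": f"{ind}_{tp}",
                        "individual_id": ind,
                        "treatment": treatment,
                        "timepoint": tp,
                    }
                )
    design = pd.DataFrame(rows)
    for treatment in TREATMENTS:
        for tp in TIMEPOINTS:
            cell = design[
                (design.treatment == treatment) & (design.timepoint == tp)
            ]
            if cell.empty:
                raise ValueError(
                    f"dropout removed every replicate of cell "
                    f"({treatment}, {tp})"
                )
    return design


@dataclass
class SimulatedExperiment:
    """Counts, lengths, design and the full planted truth of one run."""

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame
    truth: pd.DataFrame
    carrier_individuals: dict[str, frozenset]
    responder_individuals: dict[str, frozenset]


def simulate_counts(
    config: SimulationConfig, design: pd.DataFrame
) -> SimulatedExperiment:
    """Draw the count matrix and its truth table for a given design."""
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    individuals = sorted(design["individual_id"].unique())
    lps_individuals = sorted(
        design.loc[design.treatment == "LPS", "individual_id"].unique()
    )

    rng_layer = _substream(config.seed, "layers")
    n_const = int(round(config.frac_constitutive * n))
    n_never = int(round(config.frac_never_expressed * n))
    n_never = min(n_never, n - n_const)
    layers = np.array(
        ["constitutive"] * n_const
        + ["never"] * n_never
        + ["individual_specific"] * (n - n_const - n_never)
    )
    rng_layer.shuffle(layers)

    rng_mu = _substream(config.seed, "baseline_mu")
    mu = rng_mu.lognormal(config.mean_log_mu, config.sd_log_mu, size=n)
    mu[layers == "constitutive"] = np.maximum(
        mu[layers == "constitutive"], config.constitutive_mu_floor
    )

    rng_imm = _substream(config.seed, "immune")
    is_immune = rng_imm.random(n) < config.frac_immune
    boost = (layers == "constitutive") & is_immune
    mu[boost] *= config.immune_median_boost

    # per-individual carriage for individual-specific genes
    rng_car = _substream(config.seed, "carriers")
    carrier_sets: dict[str, frozenset] = {}
    carrier_mask = pd.DataFrame(
        False, index=genes, columns=individuals, dtype=bool
    )
    cm = carrier_mask.to_numpy()
    for gi in np.flatnonzero(layers == "individual_specific"):
        carried = rng_car.random(len(individuals)) < config.presence_prob
        if not carried.any():
            carried[rng_car.integers(len(individuals))] = True
        elif carried.all():
            # individual-specific means absent from >= 1 individual
            carried[rng_car.integers(len(individuals))] = False
        cm[gi] = carried
        carrier_sets[genes[gi]] = frozenset(
            ind for ind, c in zip(individuals, carried) if c
        )
    const_idx = np.flatnonzero(layers == "constitutive")
    cm[const_idx] = True
    carrier_mask = pd.DataFrame(cm, index=genes, columns=individuals)

    # responsive genes: drawn from the constitutive layer so the response
    # acts on an expressed baseline
    rng_resp = _substream(config.seed, "responsive")
    n_resp = min(config.n_responsive, len(const_idx))
    resp_idx = rng_resp.choice(const_idx, size=n_resp, replace=False)
    is_responsive = np.zeros(n, dtype=bool)
    is_responsive[resp_idx] = True
    direction = np.full(n, "", dtype=object)
    responder_sets: dict[str, frozenset] = {}
    penetrances = np.resize(
        np.atleast_1d(config.responder_penetrance).astype(float), max(n_resp, 1)
    )
    for k, gi in enumerate(resp_idx):
        direction[gi] = "down" if rng_resp.random() < config.prob_down else "up"
        n_responders = int(round(penetrances[k] * len(lps_individuals)))
        if penetrances[k] > 0:
            n_responders = max(n_responders, 1)
        chosen = rng_resp.choice(
            len(lps_individuals), size=n_responders, replace=False
        )
        responder_sets[genes[gi]] = frozenset(
            lps_individuals[i] for i in chosen
        )

    # mean matrix: genes x samples
    sample_ids = design["sample_id"].tolist()
    mean_mat = np.zeros((n, len(sample_ids)))
    for sj, row in enumerate(design.itertuples(index=False)):
        col = mu * cm[:, individuals.index(row.individual_id)]
        if row.treatment == "LPS":
            for gi in resp_idx:
                gene = genes[gi]
                if row.individual_id in responder_sets[gene]:
                    sign = -1.0 if direction[gi] == "down" else 1.0
                    col[gi] = col[gi] * 2.0 ** (sign * config.effect_log2fc)
        mean_mat[:, sj] = col

    rng_counts = _substream(config.seed, "counts")
    counts = np.zeros_like(mean_mat, dtype=np.int64)
    positive = mean_mat > 0
    if config.dispersion < 1e-9:
        counts[positive] = rng_counts.poisson(mean_mat[positive])
    else:
        shape = 1.0 / config.dispersion
        lam = rng_counts.gamma(
            shape, mean_mat[positive] * config.dispersion
        )
        counts[positive] = rng_counts.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    rng_len = _substream(config.seed, "lengths")
    lengths = pd.Series(
        np.maximum(
            np.round(
                rng_len.lognormal(
                    config.length_mean_log, config.length_sd_log, size=n
                )
            ),
            100.0,
        ),
        index=genes,
        name="length",
    )

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "layer": layers,
            "is_immune": is_immune,
            "receptor_family": "none",
            "is_responsive": is_responsive,
            "response_direction": direction,
            "responder_individuals": [
                ",".join(sorted(responder_sets.get(g, ()))) for g in genes
            ],
            "carrier_individuals": [
                ",".join(sorted(carrier_sets[g]))
                if g in carrier_sets
                else (",".join(individuals) if lay == "constitutive" else "")
                for g, lay in zip(genes, layers)
            ],
        }
    ).set_index("gene_id")
    return SimulatedExperiment(
        counts=counts_df,
        lengths=lengths,
        design=design,
        truth=truth,
        carrier_individuals=carrier_sets,
        responder_individuals=responder_sets,
    )


def _family_architecture(
    family: str, rng: np.random.Generator
) -> tuple[list[tuple[str, str]], bool]:
    """Accession list + has_tm flag satisfying exactly one family rule."""
    if family == "TLR_like":
        return [(dom.TIR, "TIR"), (dom.IG_LIKE, "ig"), (dom.IG_LIKE, "ig")], True
    if family == "TIR_only":
        return [(dom.TIR, "TIR")], bool(rng.random() < 0.5)
    if family == "NLR_bona_fide":
        return (
            [(dom.NACHT, "NACHT")] + [(dom.LRR, "LRR_6")] * int(rng.integers(1, 4)),
            False,
        )
    if family == "NACHT_only":
        return [(dom.NACHT, "NACHT"), ("PF00531", "DEATH")], False
    if family == "GPCR_GPS_7TM":
        return [(dom.GPS, "GPS"), ("PF00001", "7tm_1")], True
    if family == "GPCR_7TM":
        return [("PF00001", "7tm_1")], True
    if family == "SRCR":
        acc = "PF00530" if rng.random() < 0.7 else "PF15494"
        return [(acc, _DOMAIN_NAMES[acc])] * int(rng.integers(1, 4)), bool(
            rng.random() < 0.5
        )
    if family == "CTLD":
        return [(dom.CTL, "Lectin_C")], bool(rng.random() < 0.5)
    raise KeyError(family)


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Plant receptor architectures over the gene universe.

    Returns the long-format domain table, the per-transcript tm/signal flag
    table, and the per-gene planted family (Series over all gene ids, "none"
    for non-receptors). Replaying the table through the rule engine
    reproduces the planted families exactly.
    """
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    rng = _substream(config.seed, "annotations")
    per_family = config.n_receptors_per_family
    needed = per_family * len(dom.FAMILIES)
    if needed > n:
        raise ValueError(
            f"{needed} receptor genes requested but only {n} genes simulated"
        )
    receptor_idx = rng.choice(n, size=needed, replace=False)
    family_of = pd.Series("none", index=genes, name="receptor_family")
    rows = []
    flags = []
    assigned = {}
    for k, gi in enumerate(receptor_idx):
        assigned[genes[gi]] = dom.FAMILIES[k % len(dom.FAMILIES)]
    for gene in genes:
        family = assigned.get(gene, "none")
        family_of[gene] = family
        if family == "none":
            n_hits = int(rng.integers(0, 5))
            arch = [
                _INNOCUOUS_DOMAINS[i]
                for i in rng.integers(0, len(_INNOCUOUS_DOMAINS), size=n_hits)
            ]
            has_tm = bool(rng.random() < 0.3)
        else:
            arch, has_tm = _family_architecture(family, rng)
        pos = int(rng.integers(1, 40))
        for acc, name in arch:
            length = int(rng.integers(40, 200))
            rows.append(
                {
                    "transcript_id": gene,
                    "accession": acc,
                    "name": name,
                    "start": pos,
                    "end": pos + length,
                    "evalue": float(10.0 ** -rng.uniform(6, 30)),
                }
            )
            pos += length + int(rng.integers(5, 60))
        # occasional weak decoy hit above the e-value cutoff; must be ignored
        if family == "none" and rng.random() < 0.05:
            rows.append(
                {
                    "transcript_id": gene,
                    "accession": dom.NACHT,
                    "name": "NACHT",
                    "start": pos,
                    "end": pos + 120,
                    "evalue": float(10.0 ** -rng.uniform(0, 4)),
                }
            )
        flags.append(
            {
                "transcript_id": gene,
                "has_tm": has_tm,
                "has_signal": bool(rng.random() < 0.2),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "accession", "name", "start", "end", "evalue"],
    )
    return table, pd.DataFrame(flags), family_of
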