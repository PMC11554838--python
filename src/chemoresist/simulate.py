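"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes — not the marginal distributions of any real cohort:

* :func:`gen_rppa` — raw RPPA intensities with antibody- and
  sample-level location effects plus a group-specific log2 shift in a
  planted pathway's regulators (``2**(mu_a + nu_s + delta + eps)``).
* :func:`gen_paired` — normalized pre/post-treatment cohorts in which a
  subset of patients ("responders") up-shifts a pathway post-treatment.
* :func:`gen_survival` — an expression-linked survival cohort: High
  samples (drawn first, so truth labels are exact) carry a large shift
  in one panel gene and an exponential event hazard multiplied by the
  hazard ratio; censoring is independent exponential.
* :func:`gen_growth` — exponential tumor growth ``V0 * exp(rate * (1 -
  multiplier * treated) * t)`` with lognormal start volumes inside the
  inclusion window, multiplicative measurement noise, and caliper axes
  back-computed so ``W^2 * L * 0.5`` reproduces the volume.
* :func:`gen_edges` — an edge list with planted high-degree hubs at
  confidence 0.95 over a low-confidence background.

All generators are pure functions of ``(config.seed, parameters)``:
each draws from a named substream of the seed, so adding a generator
never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LINEAR, LOG2, AnalyteMatrix, InvariantError, RunConfig, SignedGeneSet
from .growth import GrowthSeries
from .network import EdgeList
from .survival import HIGH, LOW, SurvivalCohort

_STREAMS = {"rppa": 11, "survival": 13, "growth": 17, "paired": 19, "edges": 23}

#: survival times are rounded to this resolution (months) to exercise tie handling
TIME_RESOLUTION = 0.1


def _rng(config: RunConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


@dataclass
class SimTruth:
    """Ground truth planted by a generator.

    Only the fields relevant to the generating call are populated;
    ``params`` echoes scalar generator parameters.
    """

    group_labels: dict[str, str] | None = None
    shifted_pathways: dict[str, tuple[str, float]] | None = None
    pathways: list[SignedGeneSet] | None = None
    responder_ids: list[str] | None = None
    pairing: dict[str, tuple[str, str]] | None = None
    true_high_labels: dict[str, str] | None = None
    true_hazard_ratio: float | None = None
    planted_hubs: list[str] | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RPPA


def gen_rppa(config: RunConfig,
             n_analytes: int = 100,
             n_samples_per_group: int = 6,
             antibody_effect_sd: float = 1.0,
             sample_effect_sd: float = 0.5,
             noise_sd: float = 0.25,
             shift: float = 1.0,
             n_pathway_pos: int = 5,
             n_pathway_neg: int = 1,
             mouse_fraction: float = 0.1,
             phospho_fraction: float = 0.2) -> tuple[AnalyteMatrix, SimTruth]:
    """Raw (linear-scale) RPPA intensities for a sensitive/resistant pair.

    ``value(a, s) = 2**(mu_a + nu_s + delta + eps)`` with
    ``mu_a ~ N(0, antibody_effect_sd)``, ``nu_s ~ N(0, sample_effect_sd)``,
    ``eps ~ N(0, noise_sd)`` and ``delta`` equal to ``+shift`` for the
    planted pathway's positive regulators (``-shift`` for its negative
    regulators) in the "resistant" group only. A trailing slice of
    analytes is flagged ``species=mouse``; pathway members are human.
    """
    if n_analytes < 1 or n_samples_per_group < 1:
        raise InvariantError("need at least one analyte and one sample per group")
    for name, sd in (("antibody_effect_sd", antibody_effect_sd),
                     ("sample_effect_sd", sample_effect_sd), ("noise_sd", noise_sd)):
        if sd < 0:
            raise InvariantError(f"{name} must be >= 0, got {sd}")
    if n_pathway_pos + n_pathway_neg > n_analytes:
        raise InvariantError("pathway larger than the matrix")

    rng = _rng(config, "rppa")
    width = len(str(n_analytes))
    analytes = [f"P{i + 1:0{width}d}" for i in range(n_analytes)]
    sens = [f"sens_{i + 1:02d}" for i in range(n_samples_per_group)]
    res = [f"res_{i + 1:02d}" for i in range(n_samples_per_group)]
    samples = sens + res
    groups = {s: "sensitive" for s in sens} | {s: "resistant" for s in res}

    pos = analytes[:n_pathway_pos]
    neg = [f"{a}_pY" for a in analytes[n_pathway_pos:n_pathway_pos + n_pathway_neg]]
    analytes[n_pathway_pos:n_pathway_pos + n_pathway_neg] = neg
    pathway = SignedGeneSet("pathway1", pos, neg)

    n_mouse = int(round(mouse_fraction * n_analytes))
    n_mouse = min(n_mouse, n_analytes - len(pathway.members))
    species = ["human"] * n_analytes
    for i in range(n_analytes - n_mouse, n_analytes):
        species[i] = "mouse"
    n_phospho = int(round(phospho_fraction * n_analytes))
    is_phospho = np.zeros(n_analytes, dtype=bool)
    is_phospho[n_pathway_pos:n_pathway_pos + n_pathway_neg] = True  # the _pY members
    extra = max(0, n_phospho - int(is_phospho.sum()))
    pool = np.arange(n_pathway_pos + n_pathway_neg, n_analytes)
    if extra and len(pool):
        is_phospho[rng.choice(pool, size=min(extra, len(pool)), replace=False)] = True

    mu = rng.normal(0.0, antibody_effect_sd, size=n_analytes)
    nu = rng.normal(0.0, sample_effect_sd, size=len(samples))
    eps = rng.normal(0.0, noise_sd, size=(n_analytes, len(samples)))
    delta = np.zeros((n_analytes, len(samples)))
    res_cols = np.array([groups[s] == "resistant" for s in samples])
    pos_rows = np.isin(analytes, pos)
    neg_rows = np.isin(analytes, neg)
    delta[np.ix_(pos_rows, res_cols)] = shift
    delta[np.ix_(neg_rows, res_cols)] = -shift

    log2_values = mu[:, None] + nu[None, :] + delta + eps
    values = pd.DataFrame(2.0 ** log2_values, index=analytes, columns=samples)
    meta = pd.DataFrame({"species": species, "is_phospho": is_phospho}, index=analytes)
    matrix = AnalyteMatrix(values, scale=LINEAR, analyte_meta=meta)
    truth = SimTruth(
        group_labels=groups,
        shifted_pathways={"pathway1": ("resistant", float(shift))},
        pathways=[pathway],
        params={"n_analytes": n_analytes, "n_samples_per_group": n_samples_per_group,
                "shift": float(shift), "noise_sd": float(noise_sd)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival


def gen_survival(config: RunConfig,
                 n: int = 40,
                 genes: tuple[str, ...] = ("SRC", "FYN", "YES1"),
                 hr: float = 3.2,
                 baseline_hazard: float = 0.0066,
                 censor_rate: float = 0.001,
                 high_fraction: float = 0.6,
                 expr_shift: float = 3.0,
                 expr_sd: float = 1.0,
                 n_background_genes: int = 5) -> tuple[AnalyteMatrix, SurvivalCohort, SimTruth]:
    """Expression-linked survival cohort with a known hazard ratio.

    High labels are drawn first (Bernoulli ``high_fraction``), so truth
    labels are exact; each High sample then receives ``expr_shift`` log2
    units on one randomly chosen panel gene, which pushes it past the
    q-quantile-union threshold. Event times are exponential with rate
    ``baseline_hazard * hr**High`` per month, censoring is independent
    exponential at ``censor_rate``, observed time is the minimum, and
    times are rounded to 0.1 month to exercise tie handling.
    """
    genes = tuple(str(g) for g in genes)
    if not genes:
        raise InvariantError("gene panel must be non-empty")
    if n < 2:
        raise InvariantError(f"need n >= 2, got {n}")
    if hr <= 0:
        raise InvariantError(f"hazard ratio must be > 0, got {hr}")
    if baseline_hazard <= 0 or censor_rate <= 0:
        raise InvariantError("baseline_hazard and censor_rate must be > 0")
    if not 0 < high_fraction < 1:
        raise InvariantError(f"high_fraction must be in (0,1), got {high_fraction}")

    rng = _rng(config, "survival")
    samples = [f"pt_{i + 1:03d}" for i in range(n)]
    high = rng.random(n) < high_fraction

    background = [f"BG{i + 1:02d}" for i in range(n_background_genes)]
    all_genes = list(genes) + background
    expr = rng.normal(8.0, expr_sd, size=(len(all_genes), n))
    chosen = rng.integers(0, len(genes), size=n)
    for j in np.nonzero(high)[0]:
        expr[chosen[j], j] += expr_shift
    matrix = AnalyteMatrix(pd.DataFrame(expr, index=all_genes, columns=samples), scale=LOG2)

    hazard = baseline_hazard * np.where(high, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / censor_rate, size=n)
    observed = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    observed = np.maximum(np.round(observed / TIME_RESOLUTION) * TIME_RESOLUTION,
                          TIME_RESOLUTION)

    records = pd.DataFrame({"sample_id": samples, "time": observed, "event": event})
    labels = pd.Series(np.where(high, HIGH, LOW), index=samples)
    cohort = SurvivalCohort(records, group=labels)
    truth = SimTruth(
        true_high_labels=dict(labels),
        true_hazard_ratio=float(hr),
        params={"n": n, "baseline_hazard": baseline_hazard, "censor_rate": censor_rate,
                "high_fraction": high_fraction, "expr_shift": expr_shift},
    )
    return matrix, cohort, truth


# ---------------------------------------------------------------------------
# Growth


def gen_growth(config: RunConfig,
               n_per_arm: int = 7,
               growth_rate: float = 0.05,
               treatment_multiplier: float = 0.5,
               days: tuple[int, ...] = (0, 4, 7, 11, 14, 18, 21),
               v0_log_mean: float = float(np.log(110.0)),
               v0_log_sd: float = 0.3,
               noise_sd: float = 0.05,
               aspect_ratio: float = 1.3) -> tuple[list[GrowthSeries], SimTruth]:
    """Exponential growth curves for a control and a treated arm.

    ``volume(t) = V0 * exp(growth_rate * (1 - multiplier * treated) * t)``
    with lognormal V0 resampled into the inclusion window and
    multiplicative lognormal measurement noise at days > 0; caliper
    length/width are back-computed at a fixed aspect ratio so
    ``W^2 * L * 0.5`` reproduces the noisy volume exactly.
    """
    if not 0 <= treatment_multiplier <= 2:
        raise InvariantError(f"treatment multiplier outside [0, 2]: {treatment_multiplier}")
    days = tuple(int(d) for d in days)
    if len(days) < 2 or days[0] != 0:
        raise InvariantError("measurement schedule must start at treatment day 0")
    if n_per_arm < 1:
        raise InvariantError("need at least one animal per arm")

    rng = _rng(config, "growth")
    lo, hi = config.auc_inclusion_window
    t = np.asarray(days, dtype=float)
    series: list[GrowthSeries] = []
    for arm, treated in (("control", False), ("treated", True)):
        rate = growth_rate * (1.0 - (treatment_multiplier if treated else 0.0))
        for i in range(n_per_arm):
            v0 = 0.0
            for _ in range(1000):
                v0 = float(rng.lognormal(v0_log_mean, v0_log_sd))
                if lo < v0 <= hi:
                    break
            else:  # pragma: no cover - window/v0 parameters grossly inconsistent
                raise InvariantError(f"could not draw V0 inside ({lo}, {hi}]")
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(t)))
            noise[0] = 1.0  # the start measurement defines V0
            volumes = v0 * np.exp(rate * t) * noise
            widths = (2.0 * volumes / aspect_ratio) ** (1.0 / 3.0)
            lengths = aspect_ratio * widths
            series.append(GrowthSeries.from_caliper(f"{arm[:4]}_{i + 1:02d}", arm,
                                                    days, lengths, widths))
    truth = SimTruth(
        group_labels={s.animal_id: s.arm for s in series},
        params={"growth_rate": growth_rate, "treatment_multiplier": treatment_multiplier,
                "n_per_arm": n_per_arm, "noise_sd": noise_sd},
    )
    return series, truth


# ---------------------------------------------------------------------------
# Paired pre/post cohort


def gen_paired(config: RunConfig,
               n_patients: int = 10,
               n_responders: int = 6,
               shift: float = 2.0,
               n_extra_pre: int = 2,
               pathway_name: str = "SFK",
               n_background: int = 20,
               noise_sd: float = 0.3) -> tuple[AnalyteMatrix, AnalyteMatrix, SimTruth]:
    """Normalized pre/post-treatment matrices with planted responders.

    Responders' post-treatment samples shift every positive regulator
    of the planted pathway by ``+shift`` log2 units (negative
    regulators by ``-shift``), so their true delta-PAS equals
    ``(n_pos + n_neg) * shift``. Non-responders' pathway members are
    carried into the post sample unchanged (background analytes are
    redrawn with noise), so the Up/Down truth labels are exact by
    construction. ``n_extra_pre`` unpaired screening-only samples
    mirror cohorts where fewer patients reach surgery than screening.
    """
    if n_patients < 1:
        raise InvariantError("need at least one patient")
    if not 0 <= n_responders <= n_patients:
        raise InvariantError(f"n_responders must be in [0, {n_patients}], got {n_responders}")
    if noise_sd < 0:
        raise InvariantError("noise_sd must be >= 0")

    rng = _rng(config, "paired")
    pos = ["SRC", "FYN", "LYN", "YES1"]
    neg = ["SRC_pY527"]
    pathway = SignedGeneSet(pathway_name, pos, neg)
    background = [f"B{i + 1:02d}" for i in range(n_background)]
    analytes = pathway.members + background

    patients = [f"pt{i + 1:02d}" for i in range(n_patients)]
    responders = patients[:n_responders]
    pre_ids = [f"NASC_{p}" for p in patients] + [f"NASC_x{i + 1:02d}" for i in range(n_extra_pre)]
    post_ids = [f"NA25_{p}" for p in patients]
    pairing = {p: (f"NASC_{p}", f"NA25_{p}") for p in patients}

    base = rng.normal(0.0, 1.0, size=(len(analytes), n_patients + n_extra_pre))
    pre_vals = base + rng.normal(0.0, noise_sd, size=base.shape)
    post_vals = base[:, :n_patients] + rng.normal(0.0, noise_sd, size=(len(analytes), n_patients))
    pos_rows = np.isin(analytes, pos)
    neg_rows = np.isin(analytes, neg)
    member_rows = pos_rows | neg_rows
    # pathway members carry their pre values into post unchanged except for the
    # responder shift: Up/Down truth is exact by construction, never noise-flipped
    post_vals[member_rows, :] = pre_vals[member_rows, :n_patients]
    resp_cols = np.isin(patients, responders)
    post_vals[np.ix_(pos_rows, resp_cols)] += shift
    post_vals[np.ix_(neg_rows, resp_cols)] -= shift

    pre = AnalyteMatrix(pd.DataFrame(pre_vals, index=analytes, columns=pre_ids), scale=LOG2)
    post = AnalyteMatrix(pd.DataFrame(post_vals, index=analytes, columns=post_ids), scale=LOG2)
    truth = SimTruth(
        responder_ids=list(responders),
        pairing=pairing,
        pathways=[pathway],
        shifted_pathways={pathway_name: ("responders", float(shift))},
        params={"n_patients": n_patients, "n_responders": n_responders,
                "shift": float(shift), "noise_sd": noise_sd},
    )
    return pre, post, truth


# ---------------------------------------------------------------------------
# Edge lists


def gen_edges(config: RunConfig,
              n_genes: int = 60,
              n_hubs: int = 3,
              hub_degree: int = 5,
              hub_confidence: float = 0.95,
              background_fraction: float = 0.3,
              background_conf: tuple[float, float] = (0.3, 0.85)) -> tuple[EdgeList, SimTruth]:
    """Edge list with planted high-degree hubs over a low-confidence background.

    Each hub connects to ``hub_degree`` distinct non-hub leaves at
    confidence ``hub_confidence``; leaves are never reused, so every
    non-hub node has high-confidence degree <= 1. Background edges pair
    leftover leaves at confidences below the 0.9 floor.
    """
    if n_hubs < 0 or hub_degree < 1:
        raise InvariantError("need n_hubs >= 0 and hub_degree >= 1")
    if n_hubs * hub_degree > n_genes - n_hubs:
        raise InvariantError(
            f"{n_hubs} hub(s) of degree {hub_degree} need {n_hubs * hub_degree} distinct "
            f"leaves but only {n_genes - n_hubs} non-hub gene(s) exist"
        )
    if not 0 <= background_conf[0] <= background_conf[1] < 0.9:
        raise InvariantError("background confidences must stay below the 0.9 floor")

    rng = _rng(config, "edges")
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    hubs = genes[:n_hubs]
    leaves = genes[n_hubs:]
    shuffled = list(leaves)
    rng.shuffle(shuffled)

    rows = []
    k = 0
    for h in hubs:
        for _ in range(hub_degree):
            rows.append({"gene_a": h, "gene_b": shuffled[k], "confidence": hub_confidence})
            k += 1
    unused = shuffled[k:]
    n_bg = int(background_fraction * len(unused)) // 2 * 2
    for i in range(0, n_bg, 2):
        conf = float(rng.uniform(*background_conf))
        rows.append({"gene_a": unused[i], "gene_b": unused[i + 1], "confidence": conf})
    edges = EdgeList(pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]))
    truth = SimTruth(
        planted_hubs=list(hubs),
        params={"n_genes": n_genes, "n_hubs": n_hubs, "hub_degree": hub_degree},
    )
    return edges, truth
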