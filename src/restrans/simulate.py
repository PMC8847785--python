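"""Synthetic common-garden microbiome datasets with planted ground truth.

The generator emulates the study design this package targets: six host
populations, five field samples each, and a shared common-garden phase
sampled at 24 h, 48 h and weekly for six weeks (days 1, 2, 7, 14, 21, 28,
35, 42), four garden samples per population per timepoint, each drawn
from one of four replicate tanks — 222 samples in total.

Three ASV classes are planted:

* **resident** — presence probability ``p_present_resident`` in the home
  population (field and garden alike: residents persist through the
  garden) and ``p_leak`` elsewhere;
* **core** — probability ``p_present_core`` everywhere;
* **transient** — a background scatter ``transient_base_presence``
  everywhere, plus one *pulse window* per ASV: a run of adjacent garden
  timepoints (shared by every tank, since all tanks draw the same water)
  during which garden samples pick the ASV up with probability

      q_pop(t) = cap * (1 - exp(-lambda_pop * t)),

  saturating with residence time t at rate ``exchange_rate_per_day``.
  Synchronised pulses are what make transients co-occur across
  populations more than within them (between-population same-window pair
  counts scale as m^2 versus m(m-1)/2 within), giving them flexibility
  scores below 1.

Present taxa receive at least one read; abundances follow a
negative-binomial draw around a per-ASV log-normal weight scaled to the
sample's sequencing depth. Depths are log-normal around ``mean_depth``
with a small fraction of deliberately shallow (<1000 read) samples so the
depth filter has work to do.

:func:`generate_null_dataset` strips all population structure (one
presence probability per ASV, shared by every sample) for type-I-error
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_TIMEPOINTS = (1.0, 2.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0)


@dataclass
class GeneratorConfig:
    """Study-design and planted-structure parameters (see module docs)."""

    n_populations: int = 6
    n_field_per_pop: int = 5
    garden_timepoints_days: Tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_garden_per_pop_per_timepoint: int = 4
    n_tanks_per_pop: int = 4
    n_resident_asvs_per_pop: int = 20
    n_shared_core_asvs: int = 80
    n_transient_pool_asvs: int = 200
    p_present_resident: float = 0.9
    p_leak: float = 0.02
    p_present_core: float = 0.8
    transient_base_presence: float = 0.05
    exchange_rate_per_day: Union[float, Tuple[float, ...]] = 1.0
    transient_uptake_cap: float = 0.9
    transient_window_timepoints: int = 2
    abundance_dispersion: float = 0.5
    mean_depth: float = 20000.0
    depth_log_sigma: float = 0.35
    p_shallow: float = 0.01
    shallow_depth: float = 400.0
    tank_effect: float = 0.0
    seed: int = 0

    def rates(self) -> np.ndarray:
        r = self.exchange_rate_per_day
        if np.isscalar(r):
            return np.full(self.n_populations, float(r))
        arr = np.asarray(r, dtype=float)
        if arr.size != self.n_populations:
            raise ParameterError(
                "exchange_rate_per_day must be scalar or one value per population"
            )
        return arr

    def validate(self) -> "GeneratorConfig":
        for name in ("n_populations", "n_field_per_pop",
                     "n_garden_per_pop_per_timepoint", "n_tanks_per_pop"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if (self.n_resident_asvs_per_pop < 0 or self.n_shared_core_asvs < 0
                or self.n_transient_pool_asvs < 0):
            raise ParameterError("ASV class counts must be non-negative")
        total = (self.n_resident_asvs_per_pop * self.n_populations
                 + self.n_shared_core_asvs + self.n_transient_pool_asvs)
        if total < 1:
            raise ParameterError("at least one ASV must be generated")
        for name in ("p_present_resident", "p_leak", "p_present_core",
                     "transient_base_presence", "transient_uptake_cap",
                     "p_shallow"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        tp = np.asarray(self.garden_timepoints_days, dtype=float)
        if tp.size < 1 or not np.all(np.diff(tp) > 0) or tp[0] < 0:
            raise ParameterError("garden timepoints must be strictly increasing and >= 0")
        if not (1 <= self.transient_window_timepoints <= tp.size):
            raise ParameterError("transient window must span 1..n_timepoints")
        if (self.rates() < 0).any():
            raise ParameterError("exchange rates must be non-negative")
        if self.abundance_dispersion <= 0 or self.mean_depth <= 0:
            raise ParameterError("dispersion and mean depth must be positive")
        return self

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["garden_timepoints_days"] = list(self.garden_timepoints_days)
        if not np.isscalar(d["exchange_rate_per_day"]):
            d["exchange_rate_per_day"] = list(d["exchange_rate_per_day"])
        return d


def _sample_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for p in range(config.n_populations):
        pop = f"pop{p + 1:02d}"
        for i in range(config.n_field_per_pop):
            rows.append((f"{pop}_F{i + 1}", pop, "field", np.nan, np.nan))
        for ti, t in enumerate(config.garden_timepoints_days):
            for r in range(config.n_garden_per_pop_per_timepoint):
                tank = f"{pop}_T{(r % config.n_tanks_per_pop) + 1}"
                rows.append(
                    (f"{pop}_G{ti + 1:02d}_{r + 1}", pop, "common_garden", float(t), tank)
                )
    meta = pd.DataFrame(
        rows, columns=["sample_id", "population", "source", "timepoint", "tank"]
    ).set_index("sample_id")
    return meta


def _presence_probabilities(config: GeneratorConfig, meta: pd.DataFrame,
                            rng: np.random.Generator):
    """(prob matrix samples x ASVs, asv ids, truth frame)"""
    n_res = config.n_resident_asvs_per_pop * config.n_populations
    n_core = config.n_shared_core_asvs
    n_tr = config.n_transient_pool_asvs
    n_asv = n_res + n_core + n_tr
    pops = sorted(meta["population"].unique())
    pop_idx = meta["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    t = meta["timepoint"].to_numpy(dtype=float)
    is_garden = meta["source"].to_numpy() == "common_garden"
    n_samp = len(meta)
    rates = config.rates()

    prob = np.empty((n_samp, n_asv))
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_asv)]
    classes, homes, win_lo, win_hi = [], [], [], []

    col = 0
    for a in range(n_res):
        home = a % config.n_populations
        prob[:, col] = np.where(pop_idx == home, config.p_present_resident, config.p_leak)
        classes.append("resident"); homes.append(pops[home])
        win_lo.append(np.nan); win_hi.append(np.nan)
        col += 1
    for _ in range(n_core):
        prob[:, col] = config.p_present_core
        classes.append("core"); homes.append(""); win_lo.append(np.nan); win_hi.append(np.nan)
        col += 1
    tps = np.asarray(config.garden_timepoints_days, dtype=float)
    w = config.transient_window_timepoints
    starts = rng.integers(0, tps.size - w + 1, size=n_tr)
    for a in range(n_tr):
        window = tps[starts[a]: starts[a] + w]
        in_window = is_garden & np.isin(t, window)
        q = config.transient_uptake_cap * (1.0 - np.exp(-rates[pop_idx] * t))
        p = np.where(in_window, np.maximum(q, config.transient_base_presence),
                     config.transient_base_presence)
        p[~is_garden] = config.transient_base_presence
        prob[:, col] = p
        classes.append("transient"); homes.append("")
        win_lo.append(window[0]); win_hi.append(window[-1])
        col += 1

    if config.tank_effect > 0:
        # optional per-tank presence perturbation for sensitivity studies
        tanks = meta["tank"].fillna("none").to_numpy()
        for tank in np.unique(tanks):
            if tank == "none":
                continue
            bump = rng.normal(0.0, config.tank_effect, size=n_asv)
            rows = tanks == tank
            prob[rows] = np.clip(prob[rows] + bump[None, :], 0.0, 1.0)

    truth = pd.DataFrame(
        {
            "class": classes,
            "home_population": homes,
            "window_start_day": win_lo,
            "window_end_day": win_hi,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    return prob, asv_ids, truth


def _taxonomy(asv_ids, truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic order labels: pure-resident, pure-transient, core and a
    deliberately mixed order, so order-level summaries have contrast."""
    orders = []
    for asv in asv_ids:
        cls = truth.loc[asv, "class"]
        u = rng.random()
        if cls == "resident":
            orders.append("Mixtellales" if u < 0.15 else f"Residentiales_{int(u * 3) + 1}")
        elif cls == "transient":
            orders.append("Mixtellales" if u < 0.15 else f"Transitoriales_{int(u * 3) + 1}")
        else:
            orders.append("Corellales")
    tax = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": ["Planctomycetota" if o.startswith("T") else "Proteobacteria"
                       for o in orders],
            "class": "Synthetica",
            "order": orders,
            "family": [f"fam_{o}" if rng.random() > 0.3 else "" for o in orders],
            "genus": "",
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    return tax


def _counts_from_presence(presence: np.ndarray, config: GeneratorConfig,
                          rng: np.random.Generator) -> np.ndarray:
    n_samp, n_asv = presence.shape
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_asv)
    shallow = rng.random(n_samp) < config.p_shallow
    depth = np.where(
        shallow,
        rng.lognormal(np.log(config.shallow_depth), 0.4, size=n_samp),
        rng.lognormal(np.log(config.mean_depth), config.depth_log_sigma, size=n_samp),
    )
    counts = np.zeros((n_samp, n_asv), dtype=np.int64)
    size = config.abundance_dispersion
    for i in range(n_samp):
        mask = presence[i]
        if not mask.any():
            continue
        w = weights[mask]
        mu = depth[i] * w / w.sum()
        p = size / (size + mu)
        draw = rng.negative_binomial(size, p)
        counts[i, mask] = np.maximum(draw, 1)  # presence implies >= 1 read
    return counts


def generate_dataset(config: Optional[GeneratorConfig] = None):
    """Generate (asv_table, metadata, taxonomy, truth) for the study design.

    Reproducible: the same config (including its ``seed``) yields an
    identical dataset.
    """
    config = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_frame(config)
    prob, asv_ids, truth = _presence_probabilities(config, meta, rng)
    presence = rng.random(prob.shape) < prob
    counts = _counts_from_presence(presence, config, rng)
    table = pd.DataFrame(counts, index=meta.index.copy(), columns=asv_ids)
    table.index.name = "sample_id"
    table.columns.name = "asv_id"
    taxonomy = _taxonomy(asv_ids, truth, rng)
    return table, meta, taxonomy, truth


def generate_null_dataset(config: Optional[GeneratorConfig] = None):
    """Same design, but with every trace of population structure removed.

    Each ASV gets a single presence probability shared by all samples
    (drawn once per ASV from a Beta(0.7, 2.5), giving the sparse-to-common
    spectrum typical of amplicon tables); population labels are labels
    only. Ground-truth class is ``null`` for every ASV.
    """
    config = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_frame(config)
    n_asv = (config.n_resident_asvs_per_pop * config.n_populations
             + config.n_shared_core_asvs + config.n_transient_pool_asvs)
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_asv)]
    p_asv = rng.beta(0.7, 2.5, size=n_asv)
    presence = rng.random((len(meta), n_asv)) < p_asv[None, :]
    counts = _counts_from_presence(presence, config, rng)
    table = pd.DataFrame(counts, index=meta.index.copy(), columns=asv_ids)
    table.index.name = "sample_id"
    table.columns.name = "asv_id"
    truth = pd.DataFrame(
        {
            "class": "null",
            "home_population": "",
            "window_start_day": np.nan,
            "window_end_day": np.nan,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    taxonomy = _taxonomy(asv_ids, truth, rng)
    return table, meta, taxonomy, truth
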