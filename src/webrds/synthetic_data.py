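"""Synthetic populations, webRDS recruitment simulation and fabricated
submission tables.

No data were released with web-based respondent-driven sampling (webRDS)
studies of hidden populations such as internet-using MSM, so every
downstream stage of this package is exercised on synthetic data.  This
module generates

* an attributed social network (configuration-model-style degrees, optional
  attribute homophily and province structure),
* a chain-referral recruitment forest (seeds, electronic coupons, voluntary
  participation, recruitment without replacement),
* a submissions table with contact tokens, IP tokens, timestamps,
  completion durations and self-reported 7-day network sizes, into which
  known-invalid records (underage, duplicated tokens, shared IPs, fast
  completions) are injected at configurable rates, with full bookkeeping of
  what was injected so cleaning can be validated against ground truth,
* degree-proportional random-walk samples, the idealised regime in which
  the RDSII estimator is unbiased — used as an oracle in estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigurationError, PopulationConfig, SimulationConfig
from .forest import RecruitmentForest

EDUCATION_LEVELS = ["none", "primary", "secondary", "high_school", "vocational", "university"]
# fabricated answers never state "none": near-universal schooling in the
# emulated population, and it keeps zero-injection tables clean by construction
_EDUCATION_PROBS = [0.0, 0.03, 0.08, 0.23, 0.20, 0.46]
_INCOME_LEVELS = ["low", "middle", "high"]
_INCOME_PROBS = [0.35, 0.5, 0.15]


@dataclass
class SyntheticPopulation:
    """An attributed undirected simple graph over individuals.

    ``attributes`` is indexed by individual id and carries every declared
    trait, the province, the age in years and ``true_degree`` (the graph
    degree, the quantity participants self-report with noise).
    """

    graph: nx.Graph
    attributes: pd.DataFrame

    def __post_init__(self) -> None:
        assert not any(u == v for u, v in self.graph.edges), "self-loop in population"
        deg = dict(self.graph.degree())
        if not (self.attributes["true_degree"] == pd.Series(deg)).all():
            raise ValueError("true_degree column inconsistent with graph degrees")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def largest_component(self) -> "SyntheticPopulation":
        """Induced subpopulation on the largest connected component."""
        comp = max(nx.connected_components(self.graph), key=len)
        g = self.graph.subgraph(comp).copy()
        attrs = self.attributes.loc[sorted(comp)].copy()
        attrs["true_degree"] = pd.Series(dict(g.degree()))
        return SyntheticPopulation(g, attrs)


def _degree_sequence(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_individuals
    model, params = config.degree_model, config.degree_params
    if model == "poisson":
        deg = rng.poisson(float(params.get("mean", 8.0)), size=n)
        deg = np.maximum(deg, 1)  # every individual has at least one contact
    elif model == "powerlaw":
        exponent = float(params.get("exponent", 2.5))
        if exponent <= 1.0:
            raise ConfigurationError("powerlaw exponent must exceed 1")
        deg = np.minimum(rng.zipf(exponent, size=n), n - 1)
    else:  # regular
        k = int(params.get("degree", 3))
        if k >= n:
            raise ConfigurationError(f"regular degree {k} >= n_individuals {n}")
        if (n * k) % 2 != 0:
            raise ConfigurationError(f"n*degree = {n}*{k} is odd; no regular graph exists")
        deg = np.full(n, k)
    if deg.sum() % 2 != 0:  # stub count must be even
        deg[int(rng.integers(n))] += 1
    return deg


def _draw_attributes(config: PopulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_individuals
    data: dict = {}
    for spec in config.trait_specs:
        data[spec.name] = rng.choice(spec.categories, size=n, p=spec.probabilities)
    provinces = list(config.province_distribution)
    data["province"] = rng.choice(
        provinces, size=n, p=[config.province_distribution[p] for p in provinces]
    )
    lo, hi = int(config.age_range[0]), int(config.age_range[1])
    ages = np.arange(lo, hi + 1)
    # triangular-ish discrete distribution peaked at age_mode
    w = 1.0 / (1.0 + np.abs(ages - config.age_mode) ** 1.5)
    data["age"] = rng.choice(ages, size=n, p=w / w.sum())
    return pd.DataFrame(data, index=pd.RangeIndex(n, name="individual"))


def _match_stubs(
    degrees: np.ndarray,
    attrs: pd.DataFrame,
    homophily: list,
    rng: np.random.Generator,
) -> set:
    """Configuration-model stub matching with homophily-aware rejection.

    Self-loops and multi-edges are always rejected; a cross-category pair on
    a trait with homophily h is accepted with probability 1 - h.  After the
    attempt budget is exhausted, remaining stubs are paired without the
    homophily filter so the degree sequence is honoured as far as possible.
    """
    cols = {name: attrs[name].to_numpy() for name, _ in homophily}
    hs = dict(homophily)
    stubs = list(np.repeat(np.arange(len(degrees)), degrees))
    edges: set = set()

    def accept_homophily(u: int, v: int) -> bool:
        for name, col in cols.items():
            if col[u] != col[v] and rng.random() < hs[name]:
                return False
        return True

    for use_filter in (True, False):
        budget = 25 * len(stubs) + 100
        while len(stubs) >= 2 and budget > 0:
            budget -= 1
            i = int(rng.integers(len(stubs)))
            u = stubs[i]
            stubs[i] = stubs[-1]
            stubs.pop()
            j = int(rng.integers(len(stubs)))
            v = stubs[j]
            stubs[j] = stubs[-1]
            stubs.pop()
            e = (u, v) if u < v else (v, u)
            if u == v or e in edges or (use_filter and not accept_homophily(u, v)):
                stubs.append(u)
                stubs.append(v)
                continue
            edges.add(e)
    return edges, len(stubs)


def generate_population(config: PopulationConfig, rng_seed: int) -> SyntheticPopulation:
    """Generate an attributed random network.

    Degrees follow the configured model; for every trait the probability
    that an edge joins same-category endpoints increases monotonically with
    its homophily coefficient.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    degrees = _degree_sequence(config, rng)
    attrs = _draw_attributes(config, rng)
    homophily = [(s.name, s.homophily) for s in config.trait_specs if s.homophily > 0]
    if config.province_homophily > 0:
        homophily.append(("province", config.province_homophily))
    # retry until every stub is paired (a few leftovers can be unmatchable
    # without creating self-loops/multi-edges); accept the best attempt
    best, best_left = None, None
    for _ in range(50):
        edges, leftover = _match_stubs(degrees, attrs, homophily, rng)
        if best_left is None or leftover < best_left:
            best, best_left = edges, leftover
        if leftover == 0:
            break
    edges = best
    g = nx.Graph()
    g.add_nodes_from(range(config.n_individuals))
    g.add_edges_from(edges)
    attrs["true_degree"] = pd.Series(dict(g.degree()))
    return SyntheticPopulation(g, attrs)


def same_category_edge_fraction(pop: SyntheticPopulation, trait: str) -> float:
    """Share of edges joining same-category endpoints for ``trait``."""
    col = pop.attributes[trait]
    same = sum(1 for u, v in pop.graph.edges if col[u] == col[v])
    m = pop.graph.number_of_edges()
    if m == 0:
        raise ValueError("population has no edges")
    return same / m


def simulate_recruitment(
    pop: SyntheticPopulation, config: SimulationConfig
) -> RecruitmentForest:
    """Simulate chain-referral recruitment over the population network.

    Seeds start at wave 0; each participant invites a uniform random subset
    of eligible neighbours of size at most ``coupons_per_participant``, and
    each invitee joins independently with ``participation_probability``.
    Recruitment proceeds in discrete waves until it dies out (or
    ``max_waves`` is reached).  Without replacement no individual appears
    twice; within a wave, competing invitations are resolved in recruiter
    order, first recruiter wins.  Submission times increase strictly along
    every chain.  Deterministic given ``config.rng_seed``.
    """
    if config.n_seeds > pop.n:
        raise ConfigurationError(f"n_seeds {config.n_seeds} exceeds population {pop.n}")
    rng = np.random.default_rng(config.rng_seed)
    nodes = np.array(sorted(pop.graph.nodes))
    if config.seed_selection == "by_trait":
        trait, category = config.seed_trait
        eligible = nodes[pop.attributes.loc[nodes, trait].to_numpy() == category]
        if len(eligible) < config.n_seeds:
            raise ConfigurationError(
                f"only {len(eligible)} individuals with {trait}={category!r}; "
                f"cannot select {config.n_seeds} seeds"
            )
    else:
        eligible = nodes
    seed_people = list(rng.choice(eligible, size=config.n_seeds, replace=False))

    parent: dict = {}
    wave: dict = {}
    timestamp: dict = {}
    person: dict = {}
    sampled: set = set()
    counter = 0

    def new_node(p_id):
        nonlocal counter
        if config.with_replacement:
            nid = f"s{counter:05d}"
            counter += 1
        else:
            nid = int(p_id)
        person[nid] = int(p_id)
        return nid

    frontier = []
    for p_id in seed_people:
        nid = new_node(p_id)
        parent[nid] = None
        wave[nid] = 0
        timestamp[nid] = float(rng.uniform(0.0, 2.0))
        sampled.add(int(p_id))
        frontier.append(nid)

    w = 0
    while frontier and (config.max_waves is None or w < config.max_waves):
        nxt = []
        # deterministic recruiter order within a wave: by submission time
        for rec in sorted(frontier, key=lambda v: (timestamp[v], str(v))):
            neigh = sorted(pop.graph.neighbors(person[rec]))
            if not config.with_replacement:
                neigh = [v for v in neigh if v not in sampled]
            if not neigh or config.coupons_per_participant == 0:
                continue
            k = min(config.coupons_per_participant, len(neigh))
            invited = rng.permutation(neigh)[:k]
            for cand in invited:
                if not config.with_replacement and cand in sampled:
                    continue  # claimed earlier in this wave
                if rng.random() >= config.participation_probability:
                    continue
                nid = new_node(cand)
                parent[nid] = rec
                wave[nid] = w + 1
                timestamp[nid] = timestamp[rec] + 0.01 + float(rng.exponential(1.5))
                sampled.add(int(cand))
                nxt.append(nid)
        frontier = nxt
        w += 1
    return RecruitmentForest(parent=parent, wave=wave, timestamp=timestamp, person=person)


def random_walk_sample(
    pop: SyntheticPopulation, n_draws: int, rng_seed: int, burn_in: int = 200
) -> list:
    """Stationary simple random walk on the population graph.

    After burn-in the walk visits node i with frequency degree(i)/sum of
    degrees, the inclusion regime in which the inverse-degree (RDSII)
    estimator is unbiased.  Requires a connected graph.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if not nx.is_connected(pop.graph):
        sizes = sorted((len(c) for c in nx.connected_components(pop.graph)), reverse=True)
        raise ValueError(
            f"graph is disconnected ({len(sizes)} components of sizes {sizes[:5]}...); "
            "random walk sampling requires a connected graph"
        )
    rng = np.random.default_rng(rng_seed)
    node = int(rng.choice(sorted(pop.graph.nodes)))
    draws = []
    for step in range(burn_in + n_draws):
        neigh = sorted(pop.graph.neighbors(node))
        node = int(neigh[rng.integers(len(neigh))])
        if step >= burn_in:
            draws.append(node)
    return draws


@dataclass
class FabricatedData:
    """A fabricated submissions table plus injection ground truth.

    ``injected`` maps each invalid-record kind (``underage``,
    ``duplicate_token``, ``shared_ip``, ``fast_completion``) and
    ``network_size_missing`` to the list of submission ids affected, so the
    cleaning stage can be checked against what was actually planted.
    """

    table: pd.DataFrame
    injected: dict = field(default_factory=dict)


def fabricate_submissions(
    forest: RecruitmentForest, pop: SyntheticPopulation, config: SimulationConfig
) -> FabricatedData:
    """Fabricate one submission record per forest node.

    Records carry unique contact tokens (phone, email, chat id), an IP
    token, the individual's age and trait answers, a completion duration of
    at least 3 minutes, and a reported 7-day network size — Poisson noise
    around ``network_size_fraction`` of the true degree, missing at
    ``network_size_missing_rate`` (zeros are left in and treated as missing
    downstream).  Invalid records are injected at the configured rates into
    non-seed submissions and logged in the returned bookkeeping.
    """
    unknown = [v for v in forest.nodes if forest.person[v] not in pop.graph]
    if unknown:
        raise ValueError(f"forest nodes outside population: {unknown[:5]}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), 0x5AB5]).generate_state(1)[0]
    )
    order = sorted(forest.nodes, key=lambda v: (forest.timestamp[v], str(v)))
    inj = config.invalid_injection
    injected: dict = {
        "underage": [],
        "duplicate_token": [],
        "shared_ip": [],
        "fast_completion": [],
        "network_size_missing": [],
    }
    rows = []
    for idx, node in enumerate(order):
        pid = forest.person[node]
        indiv = pop.attributes.loc[pid]
        is_seed = forest.parent[node] is None
        row = {
            "id": node,
            "recruiter_id": forest.parent[node],
            "is_seed": is_seed,
            "timestamp": forest.timestamp[node],
            "wave": forest.wave[node],
            "phone_token": "0" + "".join(rng.choice(list("0123456789"), size=9)),
            "email_token": f"user{pid}.{node}@mail.example",
            "chat_token": f"chat_{pid}_{node}",
            "ip_token": f"ip{rng.integers(0, 2**32):08x}",
            "stated_age": int(indiv["age"]),
            "education": str(rng.choice(EDUCATION_LEVELS, p=_EDUCATION_PROBS)),
            "income": str(rng.choice(_INCOME_LEVELS, p=_INCOME_PROBS)),
            "province": indiv["province"],
            "partners_6mo": int(rng.geometric(0.38)),
            "completion_minutes": float(max(3.01, rng.lognormal(np.log(9.0), 0.45))),
        }
        for spec_name in pop.attributes.columns:
            if spec_name in ("province", "age", "true_degree"):
                continue
            row[spec_name] = indiv[spec_name]
        # reported 7-day internet-using contacts: noisy fraction of degree
        size = int(rng.poisson(config.network_size_fraction * indiv["true_degree"]))
        if rng.random() < config.network_size_missing_rate:
            size = np.nan
            injected["network_size_missing"].append(node)
        row["reported_network_size"] = size

        if not is_seed:
            if rng.random() < inj.underage_rate:
                row["stated_age"] = int(rng.integers(16, 18))
                injected["underage"].append(node)
            if idx > 0 and rng.random() < inj.duplicate_token_rate:
                donor = rows[int(rng.integers(len(rows)))]
                kind = rng.choice(["phone_token", "email_token", "chat_token"])
                row[kind] = donor[kind]
                injected["duplicate_token"].append(node)
            if idx > 0 and rng.random() < inj.shared_ip_rate:
                donor = rows[int(rng.integers(len(rows)))]
                row["ip_token"] = donor["ip_token"]
                injected["shared_ip"].append(node)
            if rng.random() < inj.fast_completion_rate:
                row["completion_minutes"] = float(rng.uniform(0.5, 2.9))
                injected["fast_completion"].append(node)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("id", drop=False)
    table.index.name = None
    return FabricatedData(table=table, injected=injected)
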