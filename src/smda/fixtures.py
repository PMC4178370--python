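"""Deterministic example and random networks.

These generators make every part of the package testable without downloads:
a hand-curated urea-cycle network in a liver-cell compartment hierarchy, the
TCA-plus-collapsed-glycolysis analysis input, eight ready-to-run sample
bundles, and seeded random bipartite networks for property testing.

The hand-curated networks use canonical reaction skeletons but omit cofactor
participants (ATP, HCO3-, CoA, NAD...) so that every fixture subnetwork stays
within the brute-force oracle guard; see docs/methods.md.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .engine import (
    EnzymeObservation,
    Observation,
    PoolLabel,
    ReferenceRange,
    ReferenceRangeTable,
)
from .errors import ValidationError
from .model import (
    MetabolicNetwork,
    Participant,
    Role,
    Subnetwork,
    collapse_pathway,
    select_subnetwork,
)

__all__ = [
    "FixtureSpec",
    "make_urea_cycle_network",
    "make_tca_glycolysis_input",
    "make_random_network",
    "sample_input_bundles",
    "default_reference_ranges",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Size and wiring parameters for one seeded random network."""

    name: str = "random"
    seed: int = 0
    n_reactions: int = 6
    n_metabolites: int = 8
    n_compartments: int = 1
    reversible_fraction: float = 0.15
    extra_pool_prob: float = 0.35
    regulator_prob: float = 0.15
    enzyme_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reactions < 1 or self.n_metabolites < 2 or self.n_compartments < 1:
            raise ValidationError(
                "a random network needs >=1 reaction, >=2 metabolites and >=1 compartment"
            )
        if self.n_metabolites < self.n_compartments:
            raise ValidationError("more compartments than metabolites is infeasible")


def make_urea_cycle_network() -> MetabolicNetwork:
    """Urea cycle in a liver cell, plus two connected stub pathways.

    Compartment chain: liver cell > cytosol > mitochondrion.  The Urea Cycle
    pathway holds exactly seven reactions: the five canonical enzymatic steps
    (CPS1, OTC, ASS, ASL, arginase) and the two mitochondrial transporters
    (ornithine in, citrulline out).  Ornithine transcarbamoylase sits in the
    mitochondrion with its four canonical participant pools.  The stub
    pathways share the cytosolic aspartate pool (purine biosynthesis) and the
    mitochondrial carbamoyl-phosphate pool (pyrimidine biosynthesis) with the
    cycle.
    """
    net = MetabolicNetwork(name="urea-cycle-fixture")
    liver = net.add_compartment("liver", "liver cell")
    cytosol = net.add_compartment("cytosol", "cytosol", parent=liver)
    mito = net.add_compartment("mito", "mitochondrion", parent=cytosol)

    mets = {
        "nh3": ("Ammonia", {"NH3"}),
        "cp": ("Carbamoyl phosphate", {"CP"}),
        "orn": ("Ornithine", set()),
        "cit": ("Citrulline", set()),
        "pi": ("Phosphate", {"Pi"}),
        "asp": ("L-Aspartate", {"Aspartate"}),
        "argsuc": ("Argininosuccinate", set()),
        "arg": ("L-Arginine", {"Arginine"}),
        "fum": ("Fumarate", set()),
        "urea": ("Urea", set()),
        "imp": ("IMP", {"Inosine monophosphate"}),
        "adsuc": ("Adenylosuccinate", set()),
        "casp": ("N-Carbamoyl-L-aspartate", set()),
    }
    for mid, (name, syns) in mets.items():
        net.add_metabolite(mid, name, syns)

    p = net.get_or_create_pool
    nh3_m = p("nh3", mito)
    cp_m = p("cp", mito)
    orn_m = p("orn", mito)
    orn_c = p("orn", cytosol)
    cit_m = p("cit", mito)
    cit_c = p("cit", cytosol)
    pi_m = p("pi", mito)
    asp_c = p("asp", cytosol)
    argsuc_c = p("argsuc", cytosol)
    arg_c = p("arg", cytosol)
    fum_c = p("fum", cytosol)
    urea_c = p("urea", cytosol)
    imp_c = p("imp", cytosol)
    adsuc_c = p("adsuc", cytosol)
    casp_c = p("casp", cytosol)

    S, P = Role.SUBSTRATE, Role.PRODUCT
    cps1 = net.add_reaction(
        "cps1",
        "carbamoyl phosphate synthetase I",
        [(nh3_m, S), (cp_m, P)],
        enzymes={"Carbamoyl phosphate synthetase I"},
    )
    otc = net.add_reaction(
        "otc",
        "ornithine transcarbamoylase",
        [(cp_m, S), (orn_m, S), (cit_m, P), (pi_m, P)],
        enzymes={"Ornithine transcarbamoylase"},
    )
    orn_t = net.add_reaction(
        "orn_transport", "ornithine transporter", [(orn_c, S), (orn_m, P)]
    )
    cit_t = net.add_reaction(
        "cit_transport", "citrulline transporter", [(cit_m, S), (cit_c, P)]
    )
    ass = net.add_reaction(
        "ass",
        "argininosuccinate synthetase",
        [(cit_c, S), (asp_c, S), (argsuc_c, P)],
        enzymes={"Argininosuccinate synthetase"},
    )
    asl = net.add_reaction(
        "asl",
        "argininosuccinate lyase",
        [(argsuc_c, S), (arg_c, P), (fum_c, P)],
        enzymes={"Argininosuccinate lyase"},
    )
    arg1 = net.add_reaction(
        "arg1",
        "arginase",
        [(arg_c, S), (urea_c, P), (orn_c, P)],
        enzymes={"Arginase"},
    )
    net.add_pathway(
        "urea_cycle",
        "Urea Cycle",
        [cps1, otc, orn_t, cit_t, ass, asl, arg1],
        compartments=[cytosol, mito],
    )

    purine = net.add_reaction(
        "adss",
        "adenylosuccinate synthetase",
        [(imp_c, S), (asp_c, S), (adsuc_c, P)],
        enzymes={"Adenylosuccinate synthetase"},
    )
    net.add_pathway("purine", "Purine Biosynthesis", [purine], compartments=[cytosol])
    pyrimidine = net.add_reaction(
        "atcase",
        "aspartate transcarbamoylase",
        [(cp_m, S), (asp_c, S), (casp_c, P)],
        enzymes={"Aspartate transcarbamoylase"},
    )
    net.add_pathway(
        "pyrimidine", "Pyrimidine Biosynthesis", [pyrimidine], compartments=[cytosol, mito]
    )
    net.validate()
    return net


def make_tca_glycolysis_network() -> MetabolicNetwork:
    """Liver-cell network with an 8-reaction TCA Cycle pathway and a toy glycolysis.

    The TCA pathway starts at pyruvate dehydrogenase and lumps fumarase with
    malate dehydrogenase into one closing reaction, keeping the classic cycle
    closed (oxaloacetate regenerated) with eight reactions in total.
    """
    net = MetabolicNetwork(name="tca-glycolysis-fixture")
    liver = net.add_compartment("liver", "liver cell")
    cytosol = net.add_compartment("cytosol", "cytosol", parent=liver)
    mito = net.add_compartment("mito", "mitochondrion", parent=cytosol)

    mets = {
        "glc": ("D-Glucose", {"Glucose"}),
        "g6p": ("D-Glucose 6-phosphate", {"G6P"}),
        "pyr": ("Pyruvate", set()),
        "accoa": ("Acetyl-CoA", set()),
        "cit": ("Citrate", set()),
        "icit": ("Isocitrate", set()),
        "akg": ("2-Oxoglutarate", {"alpha-Ketoglutarate"}),
        "succoa": ("Succinyl-CoA", set()),
        "suc": ("Succinate", set()),
        "fum": ("Fumarate", set()),
        "oaa": ("Oxaloacetate", set()),
    }
    for mid, (name, syns) in mets.items():
        net.add_metabolite(mid, name, syns)

    p = net.get_or_create_pool
    glc_c = p("glc", cytosol)
    g6p_c = p("g6p", cytosol)
    pyr_c = p("pyr", cytosol)
    pyr_m = p("pyr", mito)
    accoa_m = p("accoa", mito)
    cit_m = p("cit", mito)
    icit_m = p("icit", mito)
    akg_m = p("akg", mito)
    succoa_m = p("succoa", mito)
    suc_m = p("suc", mito)
    fum_m = p("fum", mito)
    oaa_m = p("oaa", mito)

    S, P = Role.SUBSTRATE, Role.PRODUCT
    hex_r = net.add_reaction(
        "hex", "hexokinase", [(glc_c, S), (g6p_c, P)], enzymes={"Hexokinase"}
    )
    lower = net.add_reaction(
        "glyc_lower",
        "lower glycolysis (lumped)",
        [(g6p_c, S), (pyr_c, P)],
        enzymes={"Pyruvate kinase"},
    )
    net.add_pathway("glycolysis", "Glycolysis", [hex_r, lower], compartments=[cytosol])

    pdh = net.add_reaction(
        "pdh", "pyruvate dehydrogenase", [(pyr_m, S), (accoa_m, P)],
        enzymes={"Pyruvate dehydrogenase"},
    )
    cs = net.add_reaction(
        "cs", "citrate synthase", [(accoa_m, S), (oaa_m, S), (cit_m, P)],
        enzymes={"Citrate Synthase"},
    )
    aco = net.add_reaction(
        "aco", "aconitase", [(cit_m, S), (icit_m, P)], enzymes={"Aconitase"}
    )
    idh = net.add_reaction(
        "idh", "isocitrate dehydrogenase", [(icit_m, S), (akg_m, P)],
        enzymes={"Isocitrate dehydrogenase"},
    )
    kgdh = net.add_reaction(
        "kgdh", "alpha-ketoglutarate dehydrogenase", [(akg_m, S), (succoa_m, P)],
        enzymes={"alpha-Ketoglutarate dehydrogenase"},
    )
    scs = net.add_reaction(
        "scs", "succinyl-CoA synthetase", [(succoa_m, S), (suc_m, P)],
        enzymes={"Succinyl-CoA synthetase"},
    )
    sdh = net.add_reaction(
        "sdh", "succinate dehydrogenase", [(suc_m, S), (fum_m, P)],
        enzymes={"Succinate dehydrogenase"},
    )
    fum_mdh = net.add_reaction(
        "fum_mdh",
        "fumarase / malate dehydrogenase (lumped)",
        [(fum_m, S), (oaa_m, P)],
        enzymes={"Fumarase", "Malate dehydrogenase"},
    )
    net.add_pathway(
        "tca", "TCA Cycle", [pdh, cs, aco, idh, kgdh, scs, sdh, fum_mdh],
        compartments=[mito],
    )
    net.validate()
    return net


def make_tca_glycolysis_input() -> tuple[Subnetwork, list[Observation], list[EnzymeObservation]]:
    """The worked analysis input: TCA Cycle plus glycolysis collapsed to one reaction.

    The selected subnetwork is the eight TCA reactions plus a single synthetic
    reaction consuming cytosolic D-Glucose and delivering mitochondrial
    pyruvate (glycolysis and pyruvate import lumped).  The observations are a
    single available D-Glucose measurement in the cytosol of the liver cell
    and Citrate Synthase reported unavailable.
    """
    net = make_tca_glycolysis_network()
    glc_c = net.pool_of("glc", "cytosol")
    pyr_m = net.pool_of("pyr", "mitochondrion")
    collapsed = collapse_pathway(
        net, "Glycolysis", [glc_c], [pyr_m], "liver cell"
    )
    sub = select_subnetwork(net, pathways=["TCA Cycle"], collapsed=[collapsed])
    observations = [Observation(pool=glc_c, label=PoolLabel.AVAILABLE)]
    enzyme_obs = [EnzymeObservation("Citrate Synthase", "unavailable")]
    return sub, observations, enzyme_obs


def make_random_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Seeded random bipartite network, connected by construction.

    Reactions are laid down one at a time; each reaction after the first draws
    at least one participant from the already-wired pools, which keeps the
    participation graph connected.  Every metabolite ends up in at least one
    reaction.
    """
    rng = random.Random(spec.seed)
    net = MetabolicNetwork(name=f"{spec.name}-{spec.seed}")
    comps = []
    for i in range(spec.n_compartments):
        comps.append(
            net.add_compartment(f"c{i}", f"compartment {i}", parent=comps[-1] if comps else None)
        )
    pools = []
    for i in range(spec.n_metabolites):
        net.add_metabolite(f"m{i}", f"metabolite {i}")
        pools.append(net.get_or_create_pool(f"m{i}", rng.choice(comps)))
    unwired = set(range(len(pools)))
    wired: list[int] = []

    def draw(exclude: set[int], prefer_wired: bool) -> int | None:
        if prefer_wired:
            candidates = [i for i in wired if i not in exclude]
        else:
            candidates = sorted(unwired - exclude) or [
                i for i in range(len(pools)) if i not in exclude
            ]
        if not candidates:
            return None
        idx = rng.choice(candidates)
        unwired.discard(idx)
        if idx not in wired:
            wired.append(idx)
        return idx

    for r in range(spec.n_reactions):
        n_sub = min(1 + (rng.random() < spec.extra_pool_prob), len(pools) - 1)
        n_prod = min(1 + (rng.random() < spec.extra_pool_prob), len(pools) - n_sub)
        chosen: set[int] = set()
        subs: list[int] = []
        prods: list[int] = []
        first = draw(chosen, prefer_wired=r > 0)
        assert first is not None
        chosen.add(first)
        subs.append(first)
        while len(subs) < n_sub:
            pick = draw(chosen, prefer_wired=False)
            if pick is None:
                break
            chosen.add(pick)
            subs.append(pick)
        while len(prods) < max(1, n_prod):
            pick = draw(chosen, prefer_wired=False)
            if pick is None:
                break
            chosen.add(pick)
            prods.append(pick)
        if not prods:  # tiny networks: reuse a substrate slot as the product
            prods.append(subs.pop() if len(subs) > 1 else (subs[0] + 1) % len(pools))
        participants = [(pools[i], Role.SUBSTRATE) for i in subs]
        participants += [(pools[i], Role.PRODUCT) for i in prods]
        if rng.random() < spec.regulator_prob:
            reg = rng.randrange(len(pools))
            if reg not in chosen:
                role = Role.INHIBITOR if rng.random() < 0.5 else Role.ACTIVATOR
                participants.append((pools[reg], role))
        enzymes = {f"enzyme {r}"} if rng.random() < spec.enzyme_prob else set()
        net.add_reaction(
            f"r{r}",
            f"reaction {r:02d}",
            participants,
            reversible=rng.random() < spec.reversible_fraction,
            enzymes=enzymes,
        )
    # any still-unwired pool joins the last reaction as an extra product
    last = net.reactions[f"r{spec.n_reactions - 1}"]
    for idx in sorted(unwired):
        if pools[idx] not in last.pools():
            last.participants.append(Participant(pools[idx], Role.PRODUCT))
    net.reindex()
    rids = sorted(net.reactions)
    half = max(1, len(rids) // 2)
    net.add_pathway("pw0", "pathway alpha", rids[:half])
    if rids[half:]:
        net.add_pathway("pw1", "pathway beta", rids[half:])
    net.validate()
    return net


def default_reference_ranges() -> ReferenceRangeTable:
    """Plasma-style reference ranges for the fixture metabolites (mmol/L).

    Cut-points are round textbook-style values for a generic mammalian
    profile; they stand in for a live reference-database lookup.
    """
    return ReferenceRangeTable(
        [
            ReferenceRange("D-Glucose", 3.9, 5.8, 10.0),
            ReferenceRange("Pyruvate", 0.03, 0.10, 0.20),
            ReferenceRange("Citrate", 0.06, 0.14, 0.30),
            ReferenceRange("Urea", 2.5, 7.1, 15.0),
            ReferenceRange("L-Arginine", 0.04, 0.12, 0.25),
            ReferenceRange("Ornithine", 0.03, 0.11, 0.25),
            ReferenceRange("Citrulline", 0.012, 0.055, 0.12),
            ReferenceRange("Ammonia", 0.010, 0.035, 0.10),
            ReferenceRange("L-Aspartate", 0.002, 0.025, 0.08),
            ReferenceRange("Fumarate", 0.001, 0.005, 0.02),
        ]
    )


def _urea_bundle(
    name: str,
    observations_spec: Sequence[tuple[str, str, PoolLabel]],
    enzyme_obs: Sequence[EnzymeObservation] = (),
) -> tuple[str, Subnetwork, list[Observation], list[EnzymeObservation]]:
    net = make_urea_cycle_network()
    # the cycle is an open system: ammonia enters it, urea/fumarate/phosphate
    # leave it, and cytosolic ornithine exchanges with the plasma pool
    boundary = [
        net.pool_of("nh3", "mitochondrion"),
        net.pool_of("urea", "cytosol"),
        net.pool_of("fum", "cytosol"),
        net.pool_of("pi", "mitochondrion"),
        net.pool_of("orn", "cytosol"),
    ]
    sub = select_subnetwork(net, pathways=["Urea Cycle"], boundary=boundary)
    obs = [
        Observation(pool=net.pool_of(met, comp), label=label)
        for met, comp, label in observations_spec
    ]
    return name, sub, obs, list(enzyme_obs)


def sample_input_bundles() -> list[tuple[str, Subnetwork, list[Observation], list[EnzymeObservation]]]:
    """Eight named ready-to-run analysis inputs over the fixture networks.

    Bundle contents are this package's own; they emulate the kind of sample
    inputs a hosted tool would offer (a healthy profile, an enzyme deficiency,
    an accumulation pattern, ...) without claiming equivalence to any
    particular published bundle.
    """
    bundles = []
    sub, obs, eobs = make_tca_glycolysis_input()
    bundles.append(("tca-glucose-cs-unavailable", sub, obs, eobs))
    sub2, _, _ = make_tca_glycolysis_input()
    net2 = sub2.network
    obs2 = [
        Observation(pool=net2.pool_of("glc", "cytosol"), label=PoolLabel.AVAILABLE),
        Observation(pool=net2.pool_of("pyr", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net2.pool_of("accoa", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net2.pool_of("cit", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net2.pool_of("akg", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net2.pool_of("oaa", "mitochondrion"), label=PoolLabel.AVAILABLE),
    ]
    bundles.append(("tca-oxidative-profile", sub2, obs2, []))
    sub3, _, _ = make_tca_glycolysis_input()
    net3 = sub3.network
    obs3 = [
        Observation(pool=net3.pool_of("glc", "cytosol"), label=PoolLabel.ACCUMULATED),
        Observation(pool=net3.pool_of("pyr", "mitochondrion"), label=PoolLabel.UNAVAILABLE),
    ]
    bundles.append(("tca-glucose-accumulated-pyruvate-missing", sub3, obs3, []))
    sub4, _, _ = make_tca_glycolysis_input()
    net4 = sub4.network
    obs4 = [
        Observation(pool=net4.pool_of("glc", "cytosol"), label=PoolLabel.AVAILABLE),
        Observation(pool=net4.pool_of("cit", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net4.pool_of("suc", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net4.pool_of("fum", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net4.pool_of("succoa", "mitochondrion"), label=PoolLabel.AVAILABLE),
        Observation(pool=net4.pool_of("icit", "mitochondrion"), label=PoolLabel.AVAILABLE),
    ]
    bundles.append(("tca-running-profile", sub4, obs4, []))
    bundles.append(
        _urea_bundle(
            "urea-healthy-profile",
            [
                ("nh3", "mitochondrion", PoolLabel.AVAILABLE),
                ("orn", "cytosol", PoolLabel.AVAILABLE),
                ("cit", "cytosol", PoolLabel.AVAILABLE),
                ("asp", "cytosol", PoolLabel.AVAILABLE),
                ("arg", "cytosol", PoolLabel.AVAILABLE),
                ("urea", "cytosol", PoolLabel.AVAILABLE),
            ],
        )
    )
    bundles.append(
        _urea_bundle(
            "urea-otc-deficiency",
            [
                ("nh3", "mitochondrion", PoolLabel.SEVERELY_ACCUMULATED),
                ("cit", "cytosol", PoolLabel.UNAVAILABLE),
                ("orn", "cytosol", PoolLabel.AVAILABLE),
                ("urea", "cytosol", PoolLabel.UNAVAILABLE),
                ("asp", "cytosol", PoolLabel.AVAILABLE),
            ],
            [EnzymeObservation("Ornithine transcarbamoylase", "unavailable")],
        )
    )
    bundles.append(
        _urea_bundle(
            "urea-arginase-blocked",
            [
                ("nh3", "mitochondrion", PoolLabel.AVAILABLE),
                ("arg", "cytosol", PoolLabel.ACCUMULATED),
                ("urea", "cytosol", PoolLabel.UNAVAILABLE),
                ("asp", "cytosol", PoolLabel.AVAILABLE),
                ("orn", "cytosol", PoolLabel.AVAILABLE),
            ],
            [EnzymeObservation("Arginase", "unavailable")],
        )
    )
    bundles.append(
        _urea_bundle(
            "urea-aspartate-limited",
            [
                ("nh3", "mitochondrion", PoolLabel.AVAILABLE),
                ("asp", "cytosol", PoolLabel.UNAVAILABLE),
                ("cit", "cytosol", PoolLabel.ACCUMULATED),
                ("orn", "cytosol", PoolLabel.AVAILABLE),
                ("urea", "cytosol", PoolLabel.UNAVAILABLE),
            ],
        )
    )
    return bundles


def make_random_case(
    seed: int,
    max_scenarios: int = 3000,
    max_tries: int = 50,
) -> tuple[Subnetwork, list[Observation], list[EnzymeObservation]]:
    """A seeded random analysis input with cap-sized output.

    Draws a random network (3-12 reactions, a comparable number of
    metabolites, 1-3 nested compartments), selects the whole network as the
    subnetwork, and attaches 2-4 random pool observations plus, sometimes, an
    unavailable-enzyme report.  Because unconstrained inputs can have
    astronomically many consistent scenarios (the reason the engine carries a
    cap at all), candidate draws whose exact scenario count exceeds
    ``max_scenarios`` are skipped deterministically and the next derived seed
    is tried, so the result is always exhaustively enumerable in tests.
    """
    from .engine import count_scenarios

    for attempt in range(max_tries):
        rng = random.Random(seed * 1009 + attempt)
        n_r = rng.randint(3, 12)
        spec = FixtureSpec(
            name="case",
            seed=seed * 1009 + attempt,
            n_reactions=n_r,
            n_metabolites=min(14, n_r + rng.randint(1, 3)),
            n_compartments=rng.randint(1, 3),
        )
        net = make_random_network(spec)
        sub = select_subnetwork(net, pathways=list(net.pathways.values()))
        pool_ids = [p.id for p in sub.pools]
        obs = [
            Observation(
                pool=net.pools[pid],
                label=rng.choices(list(PoolLabel), weights=[2, 5, 2, 1])[0],
            )
            for pid in rng.sample(pool_ids, k=min(len(pool_ids), rng.randint(2, 4)))
        ]
        eobs = []
        enzymes = sorted({e for r in sub.reactions for e in r.enzymes})
        if enzymes and rng.random() < 0.3:
            eobs.append(EnzymeObservation(rng.choice(enzymes), "unavailable"))
        if count_scenarios(sub, obs, eobs) <= max_scenarios:
            return sub, obs, eobs
    raise ValidationError(
        f"no cap-sized random case found for seed {seed} in {max_tries} tries"
    )


FIXTURE_NAMES = ("urea_cycle", "tca_glycolysis", "random")


def make_fixture_network(name: str, seed: int = 0) -> MetabolicNetwork:
    """Build a fixture network by name (CLI helper)."""
    if name == "urea_cycle":
        return make_urea_cycle_network()
    if name == "tca_glycolysis":
        return make_tca_glycolysis_network()
    if name == "random":
        return make_random_network(FixtureSpec(seed=seed))
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
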