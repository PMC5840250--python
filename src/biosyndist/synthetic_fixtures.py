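"""Synthetic datasets shaped like the two worked examples.

``make_hypothetical_dataset`` builds 13 deterministic profiles A–M over 13
volatiles from three pathways (MEP monoterpenes, shikimate aromatics, LOX
fatty-acid derivatives).  The profile pairs are engineered so that the
characteristic divergences between the biosynthetic distance and
Bray–Curtis appear: (C, D) share pathways but no compound, (E, F) differ
only in α- vs β-pinene (products of one terpene synthase), (G, H) share a
third of their aromatics, and (I, J, K, L) share all compounds at very
different quantities.

``make_two_species_dataset`` emulates a floral-scent comparison of two
plant species: a 40-compound pool split 25/4/11 (exclusive to species A /
exclusive to species B / shared), monoterpene-dominated, with seeded
log-normal quantities per sample.  Both are synthetic stand-ins with the
published structure, not the published numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_matrices import CompoundFeatureMatrix, SampleCompoundMatrix

__all__ = ["make_hypothetical_dataset", "make_two_species_dataset"]

# --- hypothetical 13 × 13 example ------------------------------------------

MONOTERPENES = ["alpha-pinene", "beta-pinene", "beta-phellandrene", "limonene", "myrcene"]
AROMATICS = ["benzaldehyde", "benzyl alcohol", "methyl salicylate", "phenylacetaldehyde", "indole"]
FATTY_ACID_DERIVATIVES = ["hexanal", "(Z)-3-hexenol", "(Z)-3-hexenyl acetate"]
COMPOUNDS = MONOTERPENES + AROMATICS + FATTY_ACID_DERIVATIVES

_MEP_BACKBONE = ["DXS", "DXR", "MCT", "CMK", "MDS", "HDS", "HDR", "GPPS"]
_SHIK_BACKBONE = ["DAHPS", "DHQS", "DHQD", "SDH", "EPSPS", "CS"]
_LOX_BACKBONE = ["LOX", "HPL"]


def _hypothetical_enzymes() -> CompoundFeatureMatrix:
    """Enzyme incidence: pathway backbone + terminal enzyme(s) per compound.

    α- and β-pinene share their terminal terpene synthase (identical rows);
    β-phellandrene differs from them only in the final enzyme.  Benzyl
    alcohol extends benzaldehyde's chain by a reductase, and the hexenyl
    esters nest similarly within the LOX branch.
    """
    chains: dict[str, list[str]] = {
        "alpha-pinene": _MEP_BACKBONE + ["TPS-PIN"],
        "beta-pinene": _MEP_BACKBONE + ["TPS-PIN"],
        "beta-phellandrene": _MEP_BACKBONE + ["TPS-PHE"],
        "limonene": _MEP_BACKBONE + ["TPS-LIM"],
        "myrcene": _MEP_BACKBONE + ["TPS-MYR"],
        "benzaldehyde": _SHIK_BACKBONE + ["PAL", "BA-SYN"],
        "benzyl alcohol": _SHIK_BACKBONE + ["PAL", "BA-SYN", "BA-RED"],
        "methyl salicylate": _SHIK_BACKBONE + ["PAL", "SA-MT"],
        "phenylacetaldehyde": _SHIK_BACKBONE + ["AADC"],
        "indole": _SHIK_BACKBONE + ["IGL"],
        "hexanal": _LOX_BACKBONE + ["3Z2E-ISO"],
        "(Z)-3-hexenol": _LOX_BACKBONE + ["ADH"],
        "(Z)-3-hexenyl acetate": _LOX_BACKBONE + ["ADH", "AAT"],
    }
    enzymes = sorted({e for chain in chains.values() for e in chain})
    values = np.array(
        [[1 if e in chains[c] else 0 for e in enzymes] for c in COMPOUNDS],
        dtype=float,
    )
    return CompoundFeatureMatrix(COMPOUNDS, enzymes, values)


def _hypothetical_classes() -> CompoundFeatureMatrix:
    classes = ["monoterpene", "aromatic", "fatty acid derivative"]
    of = {
        **{c: "monoterpene" for c in MONOTERPENES},
        **{c: "aromatic" for c in AROMATICS},
        **{c: "fatty acid derivative" for c in FATTY_ACID_DERIVATIVES},
    }
    values = np.array(
        [[1 if of[c] == k else 0 for k in classes] for c in COMPOUNDS], dtype=float
    )
    return CompoundFeatureMatrix(COMPOUNDS, classes, values)


_PROFILES: dict[str, dict[str, float]] = {
    # A, B, M: single-pathway bouquets anchoring the extremes
    "A": {"alpha-pinene": 10, "limonene": 5, "myrcene": 3, "beta-phellandrene": 2},
    "B": {"benzaldehyde": 10, "methyl salicylate": 5, "indole": 3},
    # C vs D: monoterpene + aromatic in both, but not one shared compound
    "C": {"alpha-pinene": 8, "benzaldehyde": 4},
    "D": {"limonene": 8, "phenylacetaldehyde": 4},
    # E vs F: identical except for the swap of the two pinene isomers
    "E": {"alpha-pinene": 6, "limonene": 3, "benzaldehyde": 2},
    "F": {"beta-pinene": 6, "limonene": 3, "benzaldehyde": 2},
    # G vs H: aromatics-only bouquets sharing one third of their compounds
    "G": {"benzaldehyde": 5, "phenylacetaldehyde": 5, "indole": 2},
    "H": {"benzaldehyde": 5, "benzyl alcohol": 5, "methyl salicylate": 2},
    # I..L: same three compounds at strongly different quantities
    "I": {"alpha-pinene": 1, "myrcene": 1, "hexanal": 1},
    "J": {"alpha-pinene": 10, "myrcene": 1, "hexanal": 1},
    "K": {"alpha-pinene": 1, "myrcene": 10, "hexanal": 1},
    "L": {"alpha-pinene": 1, "myrcene": 1, "hexanal": 10},
    "M": {"hexanal": 4, "(Z)-3-hexenol": 4, "(Z)-3-hexenyl acetate": 4},
}


def make_hypothetical_dataset() -> dict[str, object]:
    """13 deterministic profiles A–M with enzyme and class annotations.

    Returns ``{"samples", "enzymes", "classes"}``; running the pipeline on
    ``samples`` + ``enzymes`` gives the enzyme-level distance, on
    ``samples`` + ``classes`` the coarse class-level one.
    """
    sample_ids = sorted(_PROFILES)
    values = np.array(
        [[_PROFILES[s].get(c, 0.0) for c in COMPOUNDS] for s in sample_ids]
    )
    samples = SampleCompoundMatrix(sample_ids, list(COMPOUNDS), values)
    return {
        "samples": samples,
        "enzymes": _hypothetical_enzymes(),
        "classes": _hypothetical_classes(),
    }


# --- two-species floral-scent example ---------------------------------------

_POOL = {
    # (pathway, n exclusive to A, n exclusive to B, n shared) per class;
    # columns sum to 25 / 4 / 11 over a 40-compound pool
    "monoterpene": (8, 1, 7),
    "sesquiterpene": (9, 0, 1),
    "aromatic": (5, 2, 2),
    "fatty acid derivative": (3, 1, 1),
}

_BACKBONES = {
    "monoterpene": [f"MEP{i}" for i in range(1, 9)],
    "sesquiterpene": [f"MVA{i}" for i in range(1, 7)],
    "aromatic": [f"SHK{i}" for i in range(1, 7)],
    "fatty acid derivative": [f"LOX{i}" for i in range(1, 3)],
}

# mean log-quantity per pathway and species: monoterpenes dominate both
# bouquets, but species A is rich in sesquiterpenes (an Asteraceae-like
# profile) while species B leans on aromatics and green-leaf volatiles and
# emits no MVA products (Brassicaceae-like)
_LOG_MEANS = {
    "A": {
        "monoterpene": 3.0,
        "sesquiterpene": 2.8,
        "aromatic": 0.5,
        "fatty acid derivative": 0.5,
    },
    "B": {
        "monoterpene": 3.0,
        "sesquiterpene": 0.0,
        "aromatic": 2.0,
        "fatty acid derivative": 1.5,
    },
}

_LOG_SIGMA = 0.8  # within-species quantitative variability of emissions


def make_two_species_dataset(
    seed: int, n_per_species: int = 9
) -> dict[str, object]:
    """Seeded two-species floral-scent dataset with a 25/4/11 compound split.

    40 compounds across four pathways; 25 occur only in species-A samples,
    4 only in species-B samples, 11 in both.  Quantities are log-normal
    around species × compound means with per-compound occupancy; every
    compound is forced to appear in at least one sample of each species
    that can emit it, so the exclusivity bookkeeping is exact by
    construction.
    """
    if n_per_species < 2:
        raise ValueError("need at least 2 samples per species")
    rng = np.random.default_rng(seed)

    compounds: list[str] = []
    compound_class: dict[str, str] = {}
    availability: dict[str, str] = {}  # "A", "B" or "AB"
    for klass, (n_a, n_b, n_ab) in _POOL.items():
        tag = {"monoterpene": "mt", "sesquiterpene": "st", "aromatic": "ar",
               "fatty acid derivative": "fad"}[klass]
        k = 0
        for group, count in (("A", n_a), ("B", n_b), ("AB", n_ab)):
            for _ in range(count):
                k += 1
                name = f"{tag}{k:02d}"
                compounds.append(name)
                compound_class[name] = klass
                availability[name] = group

    # enzyme chains: class backbone + compound-specific terminal synthase;
    # one multi-product terpene synthase shared by two monoterpenes
    chains: dict[str, list[str]] = {}
    monoterpene_ids = [c for c in compounds if compound_class[c] == "monoterpene"]
    twin_a, twin_b = monoterpene_ids[0], monoterpene_ids[1]
    for c in compounds:
        backbone = _BACKBONES[compound_class[c]]
        terminal = f"TPS-{twin_a}" if c in (twin_a, twin_b) else f"TPS-{c}"
        chains[c] = backbone + [terminal]
    enzymes = sorted({e for chain in chains.values() for e in chain})
    enz_values = np.array(
        [[1 if e in chains[c] else 0 for e in enzymes] for c in compounds],
        dtype=float,
    )
    feature_matrix = CompoundFeatureMatrix(list(compounds), enzymes, enz_values)

    sample_ids = [f"Am{i + 1}" for i in range(n_per_species)] + [
        f"Sa{i + 1}" for i in range(n_per_species)
    ]
    species = np.array(["A"] * n_per_species + ["B"] * n_per_species)
    n_samples = 2 * n_per_species
    values = np.zeros((n_samples, len(compounds)))

    for j, c in enumerate(compounds):
        allowed = availability[c]
        occupancy = 0.9 if allowed == "AB" else 0.7
        base = rng.normal(0.0, 0.5)  # compound-level offset within its pathway
        for sp in ("A", "B"):
            if sp not in allowed:
                continue
            mu = _LOG_MEANS[sp][compound_class[c]] + base
            rows = np.flatnonzero(species == sp)
            present = rng.random(len(rows)) < occupancy
            if not present.any():  # guarantee detection in this species
                present[rng.integers(len(rows))] = True
            amounts = rng.lognormal(mean=mu, sigma=_LOG_SIGMA, size=len(rows))
            values[rows, j] = np.where(present, amounts, 0.0)

    # a sample with nothing in it is not a profile; shared monoterpenes are
    # near-ubiquitous so this is vanishingly rare, but keep it impossible
    for i in range(n_samples):
        if values[i].sum() == 0:
            shared = [k for k, c in enumerate(compounds) if availability[c] == "AB"]
            j = shared[int(rng.integers(len(shared)))]
            sp = str(species[i])
            values[i, j] = float(
                rng.lognormal(mean=_LOG_MEANS[sp]["monoterpene"], sigma=_LOG_SIGMA)
            )

    samples = SampleCompoundMatrix(sample_ids, list(compounds), values)
    return {"samples": samples, "enzymes": feature_matrix, "species": species}


def compound_bookkeeping(samples: SampleCompoundMatrix, species: np.ndarray) -> dict[str, int]:
    """Counts of total / exclusive / shared compounds between two species."""
    df = pd.DataFrame(samples.values, columns=samples.compound_ids)
    labels = np.unique(species)
    if len(labels) != 2:
        raise ValueError("bookkeeping is defined for exactly 2 species")
    in_a = df[species == labels[0]].sum(axis=0) > 0
    in_b = df[species == labels[1]].sum(axis=0) > 0
    detected = in_a | in_b
    return {
        "total": int(detected.sum()),
        "exclusive_a": int((in_a & ~in_b).sum()),
        "exclusive_b": int((in_b & ~in_a).sum()),
        "shared": int((in_a & in_b).sum()),
    }
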