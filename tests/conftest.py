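import numpy as np
import pandas as pd
import pytest

from subqtl.cross import CongenicStrainDef, CrossData, GeneticMap


@pytest.fixture
def toy_map():
    """Five markers, 2 Mb apart, on chromosome 2."""
    return GeneticMap("2", [f"m{i}" for i in range(5)],
                      100.0 + 2.0 * np.arange(5), ["SNP"] * 5)


def make_cross(gmap, genotypes, *, strain="S1", sexes=None, sac=None,
               trait=None, strain_def=None):
    """Assemble a small CrossData from a raw genotype matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    if sexes is None:
        sexes = np.where(np.arange(n) % 2 == 0, "F", "M")
    if sac is None:
        sac = np.full(n, 45.0)
    if trait is None:
        trait = np.zeros(n)
    pads = {p: np.asarray(trait, float) * s
            for p, s in (("GFP", 0.4), ("MFP", 0.3), ("RFP", 0.2),
                         ("FFP", 0.1))}
    phen = pd.DataFrame(pads)
    phen["TF"] = phen.sum(axis=1)
    defs = None
    if strain_def is not None:
        defs = {strain: strain_def}
    return CrossData(gmap, [f"{strain}-{i}" for i in range(n)],
                     np.full(n, strain, dtype=object), np.asarray(sexes, dtype=object),
                     np.asarray(sac, float), genotypes, phen, defs)


@pytest.fixture
def small_strain_def():
    return CongenicStrainDef("S1", 100.0, 108.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
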