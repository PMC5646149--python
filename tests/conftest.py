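"""Shared fixtures: a hand-built no-noise cohort on a perfect phylogeny."""

import numpy as np
import pytest

from coalimpute.simulate import Cohort, HaplotypeMatrix


@pytest.fixture
def toy_cohort() -> Cohort:
    """Eight haplotypes, six sites, laid out by hand on the perfect
    phylogeny (((0,1),(2,3)),((4,5),(6,7))).

    Site carriers: s0={0..3}, s1={4..7}, s2={0,1}, s3={2,3}, s4={4,5},
    s5={6,7}.  Measured sites are s0, s2, s4; each measured-site group is
    fully identical across all six sites and contains one study and one
    reference haplotype, so template-based imputation must be perfect.
    """
    alleles = np.zeros((8, 6), dtype=np.uint8)
    alleles[0:4, 0] = 1
    alleles[4:8, 1] = 1
    alleles[0:2, 2] = 1
    alleles[2:4, 3] = 1
    alleles[4:6, 4] = 1
    alleles[6:8, 5] = 1
    haps = HaplotypeMatrix(
        ids=[f"hap_{i}" for i in range(8)],
        positions=np.arange(1, 7) * 100,
        alleles=alleles,
    )
    return Cohort(
        haps=haps,
        study_ids=np.array([0, 2, 4, 6]),
        reference_ids=np.array([1, 3, 5, 7]),
        study_pairs=np.array([[0, 2], [4, 6]]),
        reference_pairs=np.array([[1, 3], [5, 7]]),
        measured_idx=np.array([0, 2, 4]),
        masked_idx=np.array([1, 3, 5]),
    )
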