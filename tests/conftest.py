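import numpy as np
import pytest

import npfcavity as nc


@pytest.fixture
def tiny_alignment(tmp_path):
    """Three aligned sequences of length 10, with a gapped reference."""
    path = tmp_path / "aln.fasta"
    path.write_text(
        ">ref\nM-KTAWGHIL\n"
        ">seq2\nMAKTAWGH-L\n"
        ">seq3\nMVKSAWAHIL\n"
    )
    return nc.read_alignment(path)


@pytest.fixture
def benchmark_fingerprints():
    """One seed of the standard 4-group recovery benchmark, with ground truth."""
    spec = nc.synthetic.standard_fingerprint_benchmark(seed=0)
    return nc.generate_fingerprints(spec)


@pytest.fixture
def grid_structure():
    """27-residue cubic-grid toy structure, ligand 7.9 Å from residue 1."""
    return nc.generate_toy_structure(27, ligand_offset=7.9, geometry="grid")


def brute_force_near_ligand(s, cutoff, exposure, threshold):
    """All-pairs distance-scan oracle for ligand-proximity selection."""
    lig = s.coord[s.ligand_mask & s.heavy_mask]
    selected = set()
    prot = s.protein_mask & s.heavy_mask
    for i in np.flatnonzero(prot):
        r = int(s.res_id[i])
        d = np.sqrt(((lig - s.coord[i]) ** 2).sum(axis=1)).min()
        if d <= cutoff and exposure.get(r, 0.0) >= threshold:
            selected.add(r)
    return selected
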