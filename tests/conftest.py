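import numpy as np
import pytest

from aidmds import simulate
from aidmds.sequences import ReferencePair


@pytest.fixture(scope="session")
def ref():
    """Default 203-nt synthetic two-strand reference (fixed seed)."""
    return simulate.generate_reference(seed=7)


@pytest.fixture(scope="session")
def noiseless_library(ref, tmp_path_factory):
    """2000-clone noiseless paired-end library with its truth table.

    Zero PCR/sequencing error, fixed family size 3, uniform Q37: the
    caller must recover the truth table exactly from this input.
    """
    out = tmp_path_factory.mktemp("noiseless")
    model = simulate.DeaminationModel(strand_mode="both")
    clone_set = simulate.simulate_clone_mutations(ref, model, 2000, seed=11)
    seqmodel = simulate.SequencingModel(seq_error_rate=0.0, pcr_error_rate=0.0,
                                        family_size=("fixed", 3), high_fraction=1.0)
    r1, r2, truth = out / "r1.fastq", out / "r2.fastq", out / "truth.tsv"
    simulate.emit_read_families(clone_set, seqmodel, seed=12,
                                r1_path=r1, r2_path=r2, truth_path=truth)
    return {"ref": ref, "r1": r1, "r2": r2, "clone_set": clone_set,
            "truth": clone_set.truth_table()}


def per_site_truth_counts(truth, strand):
    """Truth mutations per strand-local position (for table comparison)."""
    sub = truth[truth["strand"] == strand]
    return sub.groupby("pos").size().to_dict()
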