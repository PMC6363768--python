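import pytest

from isomirdiff import RunConfig, SimConfig, run_end_to_end, simulate_dataset


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A small but complete simulated dataset: 8 precursors, 4 samples of
    5,000 reads, 2 conditions with planted fold changes."""
    outdir = tmp_path_factory.mktemp("tiny_sim")
    cfg = SimConfig(
        seed=7,
        n_precursors=8,
        library_size=5_000,
        n_de=6,
        isomirs_per_mature=4,
    )
    bundle = simulate_dataset(cfg, outdir)
    bundle["outdir"] = outdir
    bundle["cfg"] = cfg
    return bundle


@pytest.fixture(scope="session")
def tiny_run(tiny_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_run")
    config = RunConfig(
        precursor_fasta=str(tiny_bundle["precursors"]),
        mature_file=str(tiny_bundle["matures"]),
        design_table=str(tiny_bundle["design"]),
        contaminant_fasta=str(tiny_bundle["contaminants"]),
        outdir=str(outdir),
        species_code="syn",
    )
    result = run_end_to_end(config)
    result["config"] = config
    result["outdir"] = outdir
    return result
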