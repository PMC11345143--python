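import pytest

from faerspv.cli_pipeline import load_tables
from faerspv.ingest import assemble_cases, deduplicate_cases
from faerspv.synthetic_faers import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 4,000-case synthetic bundle with one planted signal."""
    config = SyntheticConfig(
        n_cases=4000, seed=11, planted_signals=((90000020, 8.0),)
    )
    return generate(config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def assembled_cases(small_bundle):
    """The small bundle parsed, deduplicated and assembled."""
    tables = load_tables(small_bundle.paths["DEMO"].parent)
    demo, _ = deduplicate_cases(tables["DEMO"])
    return assemble_cases(
        demo,
        tables["DRUG"],
        tables["REAC"],
        tables["INDI"],
        tables["THER"],
        tables["OUTC"],
        small_bundle.dictionary.synonyms,
    )


@pytest.fixture()
def tiny_dictionary_files(tmp_path):
    """Delimited PT/SMQ/synonym fixture files: 12 PTs, 2 SOCs, 2 SMQs."""
    pt_rows = ["pt_code$pt_name$soc_name"]
    for i in range(10):
        pt_rows.append(f"1000000{i}$filler term {i}$Vascular disorders")
    pt_rows.append("10071408$maternal exposure during pregnancy$"
                   "Pregnancy, puerperium and perinatal conditions")
    pt_rows.append("10073513$exposure during pregnancy$"
                   "Pregnancy, puerperium and perinatal conditions")
    pt_path = tmp_path / "pt.txt"
    pt_path.write_text("\n".join(pt_rows) + "\n")

    smq_rows = [
        "smq_code$pt_code",
        "20000186$10071408",
        "20000186$10073513",
        "20000077$10073513",
    ]
    smq_path = tmp_path / "smq.txt"
    smq_path.write_text("\n".join(smq_rows) + "\n")

    syn_rows = [
        "raw_name$ingredient",
        "lovenox$enoxaparin",
        "enoxaparin$enoxaparin",
        "fragmin$dalteparin",
        "dalteparin$dalteparin",
    ]
    syn_path = tmp_path / "syn.txt"
    syn_path.write_text("\n".join(syn_rows) + "\n")
    return pt_path, smq_path, syn_path
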