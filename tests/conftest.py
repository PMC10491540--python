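import json

import pytest

import pubtriage as pt


@pytest.fixture(scope="session")
def gen_cfg() -> pt.GeneratorConfig:
    """Default study conditions: 400 articles, 40% relevant, separable classes."""
    return pt.GeneratorConfig(seed=11, n_articles=400)


@pytest.fixture(scope="session")
def syn_corpus(gen_cfg):
    return pt.generate_corpus(gen_cfg)


@pytest.fixture(scope="session")
def trained_setup(tmp_path_factory, gen_cfg, syn_corpus):
    """A training directory, keyword file, trained artifacts, and the report."""
    root = tmp_path_factory.mktemp("trained")
    corpus, ledger = syn_corpus
    data_dir = root / "data"
    kw_file = root / "keywords.txt"
    model_dir = root / "model"
    pt.write_training_dir(corpus, data_dir)
    pt.write_keywords(pt.generator_keyword_set(gen_cfg), kw_file)
    report = pt.service_train(data_dir, kw_file, model_dir, pt.PipelineConfig(seed=3))
    return {
        "data_dir": data_dir,
        "keywords_file": kw_file,
        "model_dir": model_dir,
        "report": report,
        "corpus": corpus,
        "ledger": ledger,
    }


@pytest.fixture()
def tiny_training_dir(tmp_path):
    (tmp_path / "Positive_1.json").write_text(
        json.dumps(["Neurons were traced.", "We used Neurolucida.", "Sholl analysis."])
    )
    (tmp_path / "Negative_1.json").write_text(
        json.dumps(["Protein folding study.", "No tracing here."])
    )
    return tmp_path
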