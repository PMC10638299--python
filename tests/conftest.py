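import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from dreamgraphs import LemmaSequence, build_graph, build_lexicon_annotator


@pytest.fixture(scope="session")
def annotator():
    """The packaged deterministic Spanish toy-lexicon annotator."""
    return build_lexicon_annotator()


@pytest.fixture
def graph_of():
    """Build a speech graph straight from a lemma list."""

    def _make(lemmas, report_id="t"):
        return build_graph(LemmaSequence(report_id, tuple(lemmas),
                                         len(lemmas)))

    return _make
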