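"""Word frequencies and the sentence-adjacency co-occurrence network.

Builds the network over the most frequent content words of one simulated
condition and prints the most central words by weighted degree.
"""

from dreamgraphs import (annotate_text, build_lexicon_annotator,
                         central_words, cooccurrence_edges, default_params,
                         generate_corpus, term_frequencies)

reports, _ = generate_corpus(default_params(seed=3))
subset = [r for r in reports if r.condition == "OO"]
annotator = build_lexicon_annotator()
annotated = {r.report_id: annotate_text(r.text, annotator, r.report_id)
             for r in subset}

freqs = term_frequencies(annotated)
print("most frequent lemmas:",
      ", ".join(f"{w} ({c})" for w, c in freqs[:8]))

net = cooccurrence_edges(annotated, top_k=30)
print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges, "
      f"total weight {sum(c for *_ , c in net.edges)}")
for word, score in central_words(net, top_n=5):
    print(f"  central: {word}  (weighted-degree share {score:.3f})")

# Centrality share is a word's summed edge weight over the network's total:
# the hubs are the words the narratives keep returning to.
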