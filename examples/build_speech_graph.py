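"""Turn one dream report into a speech graph and read off its attributes.

The report text is annotated with the packaged Spanish toy lexicon, content
words (NOUN/VERB/ADJ) are kept as lemmas, consecutive lemmas become directed
edges, and fourteen structural attributes are computed.
"""

from dreamgraphs import (annotate_report, build_graph,
                         build_lexicon_annotator, compute_attributes)

TEXT = ("Soñé que volaba sobre la ciudad. Veía mi casa y la casa era grande. "
        "Sentí miedo y desperté en mi cama.")

annotator = build_lexicon_annotator()
seq = annotate_report(TEXT, annotator, report_id="demo")
print("content lemmas:", " ".join(seq.lemmas))

graph = build_graph(seq)
attrs = compute_attributes(graph)
print(f"\nN={attrs.N} nodes, E={attrs.E} directed edges "
      f"(PE={attrs.PE} parallel, L1/L2/L3={attrs.L1}/{attrs.L2}/{attrs.L3})")
print(f"LSC={attrs.LSC}, ATD={attrs.ATD:.2f}, density={attrs.density:.3f}")
print(f"diameter={attrs.diameter:.0f}, ASP={attrs.ASP:.2f}, CC={attrs.CC:.2f}, "
      f"mean betweenness={attrs.mean_betweenness:.3f}")

# Repeated lemmas (here "casa") merge into one node and create the loops
# and parallel edges that make a narrative's graph more compact.
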