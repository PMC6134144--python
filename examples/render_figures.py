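"""Render the two figure types: the class-hull layout with shift-edge
overlay, and the ternary probability plot for a cluster triplet."""

from pathlib import Path

import cellspring as cs

out = Path("scratch_figures")
out.mkdir(exist_ok=True)

ds = cs.generate_lineage(cs.LineageSpec(seed=2))
result = cs.run_pipeline(
    ds.matrix, ds.classes,
    cs.PipelineConfig(confidence=1.0, feature_selection=True, random_state=2),
)
fig1 = cs.render_layout(
    result.layout, result.graph, list(result.graph.class_labels),
    out / "layout.png", show_hulls=True, show_shift_edges=True,
    title="spring layout: hulls per cluster, shift edges along the lineage",
)
print(f"wrote {fig1} (clusters as hulls, shift edges tracing A-B-C-D-E)")

matrix, classes = cs.filter_classes(ds.matrix, ds.classes, 5)
space = cs.correlation_transform(cs.normalize_umi(matrix))
ternary, analysis, call = cs.analyze_triplet(space, classes, ("A", "B", "C"),
                                             seed=2)
fig2 = cs.render_ternary(ternary, analysis, out / "ternary.png")
print(f"wrote {fig2} (confusion score {analysis.score:.3f} -> {call}: "
      "cells line the A-B and B-C edges, so B is a transition state)")
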