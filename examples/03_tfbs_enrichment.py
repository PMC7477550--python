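"""Promoter TFBS enrichment and the cross-condition meta-analysis.

Tests every TF's quality-filtered binding sites (BBLS > 1, FDR < 0.25)
for enrichment in the -10000/+2000 promoter windows of each condition's
rhythmic genes, flags condition-exclusive TFs, and builds the focal TF's
target set from motif plus ChIP-peak evidence in -3000/+1000 windows.
"""

from rhythmix import (
    build_target_set,
    call_rhythmic,
    default_spec,
    fisher_enrichment,
    generate_motif_annotation,
    generate_timecourse,
    jtk_scan_matrix,
    meta_exclusive_tfs,
)

spec = default_spec(n_genes=1000, seed=3)
matrices, truth = generate_timecourse(spec)
annotation, sites, peaks = generate_motif_annotation(spec, truth)

rhythmic = {c: call_rhythmic(jtk_scan_matrix(m), 0.01)
            for c, m in matrices.items()}
background = set(matrices["wt_sal"].gene_ids)

denovo = rhythmic["wt_coc"] - rhythmic["wt_sal"]
records = fisher_enrichment(denovo, background, sites.tf_names(),
                            sites, annotation)
print(f"TFs ranked by -log10 p in the {len(denovo)}-gene de-novo set:")
for r in records[:5]:
    print(f"  {r.tf_name:10s} k={r.k:3d}/{r.k + r.m}  "
          f"-log10 p = {r.neg_log10_p:6.2f}")

by_cond = {c: fisher_enrichment(rhythmic[c], background, sites.tf_names(),
                                sites, annotation)
           for c in spec.conditions}
meta = meta_exclusive_tfs(by_cond, alpha_tf=0.01)
label = meta.loc[spec.focal_tf, "exclusive_to"]
print(f"\nmeta-analysis: {spec.focal_tf} is exclusive to: {label}")

targets = build_target_set(spec.focal_tf, sites, peaks, annotation)
overlap = len(targets & truth.focal_targets)
print(f"\n{spec.focal_tf} target set (motif + peak, -3000/+1000): "
      f"{len(targets)} genes, {overlap} of them planted targets")
print("The focal TF's sites were planted preferentially in de-novo "
      "promoters (p_in=0.5 vs p_out=0.05), so it should rank first and "
      "be exclusive to the treated wild-type condition.")
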