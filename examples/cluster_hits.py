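"""Structure-activity clustering with ECFP4 fingerprints.

Clusters a small demonstration set (a homologous alkane series plus three
unrelated aromatics) by Tanimoto sphere exclusion at the 0.6 cutoff.
"""

import mrgscreen as ms

smiles = {
    "alk10": "CCCCCCCCCC",
    "alk11": "CCCCCCCCCCC",
    "alk12": "CCCCCCCCCCCC",
    "phenol": "c1ccccc1O",
    "aniline": "c1ccccc1N",
    "pyridine": "c1ccncc1",
}
fps = [ms.fingerprint(smi, cid) for cid, smi in smiles.items()]
result = ms.cluster(fps, cutoff=0.6, min_report_size=3)

print(f"similarity cutoff: {result.similarity_cutoff}")
print(f"clusters with >= {result.min_report_size} members: {len(result.major_clusters)}")
for c in result.major_clusters:
    print(f"  centroid {c.centroid}: {', '.join(c.members)} "
          f"(mean similarity {c.mean_similarity:.2f})")
print(f"unclustered: {', '.join(result.unclustered)}")
# The homologous alkanes share nearly all circular substructures and form one
# cluster; the aromatics fall below the cutoff and stay unclustered.
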