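"""Predict transmembrane topology by hydropathy and print a TM-Info report.

A sliding Kyte-Doolittle window (19 residues, threshold 1.6) marks
membrane-like stretches; boundaries are refined on the raw per-residue
hydropathy.  The same report is available from the CLI via
``memsa run --tm-info``.
"""

from memsa import SequenceRecord, predict_topology, segment_sequence, tm_info

# two hydrophobic helices separated by a charged loop
seq = (
    "MSTNKEQDSR"            # N-terminal loop
    + "ILVFILLVVAILLILVFAGI"  # helix 1
    + "RKDEQNSTGR"            # cytoplasmic loop
    + "FLIVALLIVGILVLFIIVLG"  # helix 2
    + "NQSTDEKRHG"            # C-terminal loop
)
record = SequenceRecord("demo", seq)

annotation = predict_topology(record)
print(f"{annotation.tm_count} transmembrane helices predicted\n")

report = tm_info([segment_sequence(record, annotation)])
print(report.to_string(index=False))
print("\ncolumns: 1-based start/end; lengths sum to the sequence length "
      f"({report['length'].sum()} residues)")
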