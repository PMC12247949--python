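#!/usr/bin/env python
"""Screen control libraries for anomalous marker expression.

A knockdown experiment's own target genes double as quality markers: a
control library whose yki expression sits far below its peer controls
distorts every yki-related contrast. This step applies the MAD rule
(k = 3 scaled MADs around the peer-control median, per cell type) and
writes the flagged library IDs for step 03 to exclude.
"""

from pathlib import Path

from hippolink.de import flag_outlier_controls
from hippolink.io import read_counts, read_metadata

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_counts(BASE / "simulated" / "counts.tsv")
    meta = read_metadata(BASE / "simulated" / "metadata.tsv")
    flagged = flag_outlier_controls(counts, meta, marker_gene="yki", k=3.0)
    out = BASE / "flagged_controls.txt"
    out.write_text("".join(s + "\n" for s in flagged))
    if flagged:
        print(f"flagged {len(flagged)} control librar{'y' if len(flagged) == 1 else 'ies'}:")
        for s in flagged:
            print(f"  {s}")
    else:
        print("no control library flagged")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
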