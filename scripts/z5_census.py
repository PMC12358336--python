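"""Exhaustive chamber census for G = Z/5Z (long-running).

Enumerates all 2^21 sign vectors of the 21-hyperplane arrangement with
exact LP feasibility, tallies the rank census (expected: 113,352
chambers, ranks 13..21), builds the adjacency graph, and counts the
locally maximal chambers of deficient rank (expected: 1,840).

This is deliberately not part of the default test suite: it takes hours
of exact rational arithmetic on one core.  Run it directly:

    python scripts/z5_census.py [--skip-adjacency] [--out census.csv]
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

import sunletdim as sd
from sunletdim.serialize import census_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("z5_census.csv"))
    parser.add_argument("--skip-adjacency", action="store_true")
    args = parser.parse_args()

    z5 = sd.parse_group("Z5")
    t0 = time.time()
    chambers = sd.enumerate_chambers(z5, force=True)
    print(f"enumerated {len(chambers)} chambers in {time.time() - t0:.0f}s")
    c = sd.census(z5, chambers)
    frame = census_frame(c, decimals=3)
    print(frame.to_string(index=False))
    frame.to_csv(args.out, index=False)

    if not args.skip_adjacency:
        t0 = time.time()
        graph = sd.adjacency(z5, chambers)
        traps = sd.locally_maximal_deficient(chambers, graph)
        print(
            f"adjacency in {time.time() - t0:.0f}s; "
            f"{len(traps)} locally maximal deficient chambers"
        )


if __name__ == "__main__":
    main()
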