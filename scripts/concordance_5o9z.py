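#!/usr/bin/env python
"""OPTIONAL concordance check against the deposited pre-catalytic spliceosome
structure (PDB 5O9Z). Requires a locally downloaded coordinate file; nothing
in the test suite depends on this script.

The structural Y/N flags of the built-in catalogue were derived interactively
on 5O9Z with an unspecified rotamer-placement procedure, so exact flag
reproduction is not expected. Qualitative agreement IS expected for the two
inter-chain findings: Arg408Trp gaining an interaction with PRPF6, and
Gly261Arg gaining an interaction with PRPF8.

You must supply the chain -> molecule mapping for your copy of the file
(chain ids differ between assemblies), e.g.:

    python scripts/concordance_5o9z.py 5o9z.cif \
        --prpf31-chain W --entity-map entities.cfg

where entities.cfg contains lines like "W = PRPF31", "V = PRPF6",
"A = PRPF8", "S = SNU13", "U = U4 snRNA".
"""

from __future__ import annotations

import argparse
import sys


def read_entity_map(path: str) -> dict:
    mapping = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line and "=" in line:
                k, v = (p.strip() for p in line.split("=", 1))
                mapping[k] = v
    return mapping


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("structure", help="path to a local 5O9Z mmCIF/PDB file")
    parser.add_argument("--prpf31-chain", required=True,
                        help="chain id of PRPF31 in the file")
    parser.add_argument("--entity-map", required=True,
                        help="key-value file: chain id = molecule name")
    args = parser.parse_args()

    from varstruct import (analyze_variants, load_builtin_catalogue,
                           parse_structure, render_report)

    model = parse_structure(args.structure, "auto")
    entity_map = read_entity_map(args.entity_map)
    records = load_builtin_catalogue()
    result = analyze_variants(model, args.prpf31_chain, records,
                              entity_map=entity_map)
    print(render_report(result.rows, "tsv"))

    expectations = {"ARG408TRP": "PRPF6", "GLY261ARG": "PRPF8"}
    print("qualitative inter-chain concordance:")
    ok = True
    for row in result.rows:
        if row.protein in expectations:
            wanted = expectations[row.protein]
            hit = wanted in row.hbond_partners and row.affects_hbond_other == "Y"
            ok &= hit
            print(f"  {row.protein}: expected new interaction with {wanted}; "
                  f"observed partners: {row.hbond_partners or '(none)'} "
                  f"-> {'agree' if hit else 'DISAGREE'}")
    if result.failures:
        print(f"variants not modeled: {sorted(result.failures)}")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
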