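"""Build the bundled 284-gene Rab/Rab-interactor catalog fixture.

Cluster membership is exact for the Rab27 cluster (its full membership is
published); every other cluster carries the published per-role counts but is
padded with clearly-labelled synthetic placeholder interactor symbols
(SYNEF/SYNGEF/SYNGAP prefixes), with cross-cluster sharing arranged so the
role totals come out at 23 GEFs, 20 GAPs and 174 effectors (217 unique
interactors) plus 61 Rab genes and 6 general-machinery genes = 284.
"""
from collections import OrderedDict

# cluster -> (n_isoforms, n_gefs, n_gaps, n_effectors)
COUNTS = OrderedDict([
    ("RAB1", (2, 8, 1, 18)), ("RAB2", (2, 0, 3, 6)), ("RAB3", (4, 3, 3, 23)),
    ("RAB4", (2, 0, 2, 19)), ("RAB5", (3, 7, 5, 28)), ("RAB6", (3, 0, 2, 24)),
    ("RAB7", (2, 1, 1, 14)), ("RAB8", (2, 2, 2, 22)), ("RAB9", (2, 0, 0, 9)),
    ("RAB10", (1, 1, 3, 9)), ("RAB11", (2, 0, 3, 29)), ("RAB12", (1, 0, 0, 1)),
    ("RAB13", (1, 0, 0, 10)), ("RAB14", (1, 0, 1, 5)), ("RAB15", (1, 0, 0, 6)),
    ("RAB17", (1, 0, 1, 1)), ("RAB18", (1, 0, 0, 0)), ("RAB19", (1, 0, 0, 3)),
    ("RAB20", (1, 0, 0, 1)), ("RAB21", (1, 2, 1, 0)), ("RAB22", (1, 1, 2, 5)),
    ("RAB23", (1, 0, 1, 0)), ("RAB24", (1, 0, 0, 2)), ("RAB25", (1, 0, 0, 7)),
    ("RAB26", (1, 0, 0, 1)), ("RAB27", (2, 1, 1, 12)), ("RAB28", (1, 0, 0, 0)),
    ("RAB30", (1, 0, 0, 3)), ("RAB31", (1, 1, 0, 3)), ("RAB32", (1, 0, 0, 2)),
    ("RAB33", (2, 0, 0, 8)), ("RAB34", (1, 0, 1, 2)), ("RAB35", (1, 3, 1, 5)),
    ("RAB36", (1, 0, 1, 6)), ("RAB37", (1, 0, 0, 2)), ("RAB38", (1, 0, 0, 1)),
    ("RAB39", (2, 0, 1, 3)), ("RAB40", (3, 0, 0, 2)), ("RAB41", (1, 0, 1, 3)),
    ("RAB42", (1, 0, 0, 0)), ("RAB43", (1, 0, 1, 0)), ("RAB44", (1, 0, 0, 0)),
])

ISOFORMS = {
    "RAB1": ["RAB1A", "RAB1B"], "RAB2": ["RAB2A", "RAB2B"],
    "RAB3": ["RAB3A", "RAB3B", "RAB3C", "RAB3D"], "RAB4": ["RAB4A", "RAB4B"],
    "RAB5": ["RAB5A", "RAB5B", "RAB5C"], "RAB6": ["RAB6A", "RAB6B", "RAB6C"],
    "RAB7": ["RAB7A", "RAB7B"], "RAB8": ["RAB8A", "RAB8B"],
    "RAB9": ["RAB9A", "RAB9B"], "RAB11": ["RAB11A", "RAB11B"],
    "RAB22": ["RAB22A"], "RAB27": ["RAB27A", "RAB27B"],
    "RAB33": ["RAB33A", "RAB33B"], "RAB39": ["RAB39A", "RAB39B"],
    "RAB40": ["RAB40A", "RAB40B", "RAB40C"],
}

# Real interactors with fixed role and cluster placement.  The Rab27 cluster
# membership is exact; the rest are real symbols from the screen placed at
# plausible positions.
REAL = [
    # symbol, role, clusters
    ("MADD", "gef", ["RAB27"]),
    ("TBC1D10A", "gap", ["RAB27"]),
    ("EXPH5", "effector", ["RAB27"]),
    ("GCC2", "effector", ["RAB27", "RAB6"]),
    ("MLPH", "effector", ["RAB27"]),
    ("MYRIP", "effector", ["RAB27"]),
    ("RPH3A", "effector", ["RAB27"]),
    ("RPH3AL", "effector", ["RAB27"]),
    ("SYTL1", "effector", ["RAB27"]),
    ("SYTL2", "effector", ["RAB27"]),
    ("SYTL3", "effector", ["RAB27"]),
    ("SYTL4", "effector", ["RAB27"]),
    ("SYTL5", "effector", ["RAB27"]),
    ("UNC13D", "effector", ["RAB27"]),
    ("TRAPPC1", "gef", ["RAB1"]),
    ("RIN1", "gef", ["RAB5"]),
    ("CCZ1", "gef", ["RAB7"]),
    ("ANKRD27", "gef", ["RAB21"]),
    ("TBC1D30", "gap", ["RAB8"]),
    ("TBC1D4", "gap", ["RAB10", "RAB14"]),
    ("TBC1D3B", "gap", ["RAB5"]),
    ("RABGAP1L", "gap", ["RAB22"]),
    ("MICAL1", "effector", ["RAB1"]),
    ("MICAL2", "effector", ["RAB1"]),
    ("LEPRE1", "effector", ["RAB1"]),
    ("RABAC1", "effector", ["RAB1"]),
    ("ICA1", "effector", ["RAB2"]),
    ("TMEM22", "effector", ["RAB2"]),
    ("STXBP1", "effector", ["RAB3"]),
    ("UNC13B", "effector", ["RAB3"]),
    ("GNAL", "effector", ["RAB3"]),
    ("YWHAQ", "effector", ["RAB3"]),
    ("CD2AP", "effector", ["RAB4"]),
    ("SDC1", "effector", ["RAB4"]),
    ("EEA1", "effector", ["RAB5"]),
    ("CAV1", "effector", ["RAB5"]),
    ("F8A1", "effector", ["RAB5"]),
    ("KIF20A", "effector", ["RAB6"]),
    ("ZWINT", "effector", ["RAB6"]),
    ("MYO5C", "effector", ["RAB8"]),
    ("MYO5B", "effector", ["RAB11"]),
    ("RAB11FIP1", "effector", ["RAB11"]),
    ("RAB11FIP2", "effector", ["RAB11"]),
    ("REP15", "effector", ["RAB15"]),
    ("PIGR", "effector", ["RAB25"]),
    ("ITGA5", "effector", ["RAB25"]),
    ("CASP1", "effector", ["RAB39"]),
    ("GMCL1", "effector", ["RAB39"]),
]

GENERAL = ["GDI1", "GDI2", "CHM", "CHML", "RABGGTA", "RABGGTB"]

UNIQUE_TARGET = {"gef": 23, "gap": 20, "effector": 174}


def main() -> None:
    genes: "OrderedDict[str, tuple[str, list[str]]]" = OrderedDict()

    def add(symbol, role, cluster):
        if symbol in genes:
            r, cl = genes[symbol]
            assert r == role, symbol
            assert cluster not in cl
            cl.append(cluster)
        else:
            genes[symbol] = (role, [cluster])

    # Rab isoforms
    for cl, (n_iso, _, _, _) in COUNTS.items():
        iso = ISOFORMS.get(cl, [cl])
        assert len(iso) == n_iso, cl
        for sym in iso:
            add(sym, "rab", cl)

    # pre-place real interactors
    placed = {}  # (cluster, role) -> count
    for sym, role, clusters in REAL:
        for cl in clusters:
            add(sym, role, cl)
            placed[(cl, role)] = placed.get((cl, role), 0) + 1

    role_idx = {"gef": 1, "gap": 2, "effector": 3}
    prefix = {"gef": "SYNGEF", "gap": "SYNGAP", "effector": "SYNEF"}
    for role in ("gef", "gap", "effector"):
        # remaining slots per cluster in catalog order
        slots = []
        for cl, counts in COUNTS.items():
            need = counts[role_idx[role]] - placed.get((cl, role), 0)
            assert need >= 0, (cl, role)
            if cl == "RAB27":
                assert need == 0  # exact published membership
            slots.extend([cl] * need)
        n_real = sum(1 for s, r, _ in REAL if r == role)
        n_new = UNIQUE_TARGET[role] - n_real
        assert 0 <= n_new <= len(slots), (role, n_new, len(slots))
        pool = []
        for i, cl in enumerate(slots[:n_new]):
            sym = f"{prefix[role]}{i + 1:03d}"
            add(sym, role, cl)
            pool.append(sym)
        # remaining slots are shared memberships: round-robin over the
        # synthetic pool, skipping genes already in that cluster
        j = 0
        for cl in slots[n_new:]:
            for _ in range(len(pool) + 1):
                sym = pool[j % len(pool)]
                j += 1
                if cl not in genes[sym][1]:
                    genes[sym][1].append(cl)
                    break
            else:
                raise RuntimeError(f"no shareable {role} for {cl}")

    for sym in GENERAL:
        genes[sym] = ("general_machinery", [])

    # --- checks ---------------------------------------------------------
    by_role = {}
    for sym, (role, cl) in genes.items():
        by_role.setdefault(role, []).append(sym)
    assert len(genes) == 284, len(genes)
    assert len(by_role["rab"]) == 61
    assert len(by_role["gef"]) == 23
    assert len(by_role["gap"]) == 20
    assert len(by_role["effector"]) == 174
    assert len(by_role["general_machinery"]) == 6
    for cl, (n_iso, n_gef, n_gap, n_eff) in COUNTS.items():
        got = [0, 0, 0, 0]
        for sym, (role, cls) in genes.items():
            if cl in cls:
                got["rab gef gap effector".split().index(role)] += 1
        assert tuple(got) == (n_iso, n_gef, n_gap, n_eff), (cl, got)
    rab27 = [s for s, (r, c) in genes.items() if "RAB27" in c]
    assert len(rab27) == 16 and "RPH3A" in rab27

    absent = ["F8A1", "CCZ1", "GMCL1", "RAB13", "RAB19", "RAB41", "RAB43",
              "RAB44", "RAB6C", "RAB7B", "RAB9B", "REP15", "RPH3A",
              "TBC1D3B", "YWHAQ"]
    for a in absent:
        assert a in genes, a
    assert len(genes) - len(absent) == 269

    with open("src/rabscreen/data/catalog.tsv", "w") as fh:
        fh.write("symbol\trole\tclusters\n")
        for sym, (role, cls) in genes.items():
            fh.write(f"{sym}\t{role}\t{';'.join(cls)}\n")
    with open("src/rabscreen/data/u133_absent.txt", "w") as fh:
        fh.write("\n".join(absent) + "\n")
    print("catalog written:", len(genes), "genes")


if __name__ == "__main__":
    main()
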