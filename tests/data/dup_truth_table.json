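{
 "((((at,g1),g2),h1),h2)": "ASTERACEAE",
 "((((at,g1),g2),h2),h1)": "ASTERACEAE",
 "((((at,g1),h1),g2),h2)": "ASTERACEAE",
 "((((at,g1),h1),h2),g2)": "ASTERACEAE",
 "((((at,g1),h2),g2),h1)": "ASTERACEAE",
 "((((at,g1),h2),h1),g2)": "ASTERACEAE",
 "((((at,g2),g1),h1),h2)": "ASTERACEAE",
 "((((at,g2),g1),h2),h1)": "ASTERACEAE",
 "((((at,g2),h1),g1),h2)": "ASTERACEAE",
 "((((at,g2),h1),h2),g1)": "ASTERACEAE",
 "((((at,g2),h2),g1),h1)": "ASTERACEAE",
 "((((at,g2),h2),h1),g1)": "ASTERACEAE",
 "((((at,h1),g1),g2),h2)": "ASTERACEAE",
 "((((at,h1),g1),h2),g2)": "ASTERACEAE",
 "((((at,h1),g2),g1),h2)": "ASTERACEAE",
 "((((at,h1),g2),h2),g1)": "ASTERACEAE",
 "((((at,h1),h2),g1),g2)": "LINEAGE",
 "((((at,h1),h2),g2),g1)": "LINEAGE",
 "((((at,h2),g1),g2),h1)": "ASTERACEAE",
 "((((at,h2),g1),h1),g2)": "ASTERACEAE",
 "((((at,h2),g2),g1),h1)": "ASTERACEAE",
 "((((at,h2),g2),h1),g1)": "ASTERACEAE",
 "((((at,h2),h1),g1),g2)": "LINEAGE",
 "((((at,h2),h1),g2),g1)": "LINEAGE",
 "((((g1,g2),at),h1),h2)": "LINEAGE",
 "((((g1,g2),at),h2),h1)": "LINEAGE",
 "((((g1,g2),h1),at),h2)": "LINEAGE",
 "((((g1,g2),h1),h2),at)": "LINEAGE",
 "((((g1,g2),h2),at),h1)": "LINEAGE",
 "((((g1,g2),h2),h1),at)": "LINEAGE",
 "((((g1,h1),at),g2),h2)": "ASTERACEAE",
 "((((g1,h1),at),h2),g2)": "ASTERACEAE",
 "((((g1,h1),g2),at),h2)": "ASTERACEAE",
 "((((g1,h1),g2),h2),at)": "ASTERACEAE",
 "((((g1,h1),h2),at),g2)": "ASTERACEAE",
 "((((g1,h1),h2),g2),at)": "ASTERACEAE",
 "((((g1,h2),at),g2),h1)": "ASTERACEAE",
 "((((g1,h2),at),h1),g2)": "ASTERACEAE",
 "((((g1,h2),g2),at),h1)": "ASTERACEAE",
 "((((g1,h2),g2),h1),at)": "ASTERACEAE",
 "((((g1,h2),h1),at),g2)": "ASTERACEAE",
 "((((g1,h2),h1),g2),at)": "ASTERACEAE",
 "((((g2,h1),at),g1),h2)": "ASTERACEAE",
 "((((g2,h1),at),h2),g1)": "ASTERACEAE",
 "((((g2,h1),g1),at),h2)": "ASTERACEAE",
 "((((g2,h1),g1),h2),at)": "ASTERACEAE",
 "((((g2,h1),h2),at),g1)": "ASTERACEAE",
 "((((g2,h1),h2),g1),at)": "ASTERACEAE",
 "((((g2,h2),at),g1),h1)": "ASTERACEAE",
 "((((g2,h2),at),h1),g1)": "ASTERACEAE",
 "((((g2,h2),g1),at),h1)": "ASTERACEAE",
 "((((g2,h2),g1),h1),at)": "ASTERACEAE",
 "((((g2,h2),h1),at),g1)": "ASTERACEAE",
 "((((g2,h2),h1),g1),at)": "ASTERACEAE",
 "((((h1,h2),at),g1),g2)": "LINEAGE",
 "((((h1,h2),at),g2),g1)": "LINEAGE",
 "((((h1,h2),g1),at),g2)": "ASTERACEAE",
 "((((h1,h2),g1),g2),at)": "ASTERACEAE",
 "((((h1,h2),g2),at),g1)": "ASTERACEAE",
 "((((h1,h2),g2),g1),at)": "ASTERACEAE",
 "(((at,g1),(g2,h1)),h2)": "ASTERACEAE",
 "(((at,g1),(g2,h2)),h1)": "ASTERACEAE",
 "(((at,g1),(h1,h2)),g2)": "ASTERACEAE",
 "(((at,g1),g2),(h1,h2))": "ASTERACEAE",
 "(((at,g1),h1),(g2,h2))": "ASTERACEAE",
 "(((at,g1),h2),(g2,h1))": "ASTERACEAE",
 "(((at,g2),(g1,h1)),h2)": "ASTERACEAE",
 "(((at,g2),(g1,h2)),h1)": "ASTERACEAE",
 "(((at,g2),(h1,h2)),g1)": "ASTERACEAE",
 "(((at,g2),g1),(h1,h2))": "ASTERACEAE",
 "(((at,g2),h1),(g1,h2))": "ASTERACEAE",
 "(((at,g2),h2),(g1,h1))": "ASTERACEAE",
 "(((at,h1),(g1,g2)),h2)": "LINEAGE",
 "(((at,h1),(g1,h2)),g2)": "ASTERACEAE",
 "(((at,h1),(g2,h2)),g1)": "ASTERACEAE",
 "(((at,h1),g1),(g2,h2))": "ASTERACEAE",
 "(((at,h1),g2),(g1,h2))": "ASTERACEAE",
 "(((at,h1),h2),(g1,g2))": "LINEAGE",
 "(((at,h2),(g1,g2)),h1)": "LINEAGE",
 "(((at,h2),(g1,h1)),g2)": "ASTERACEAE",
 "(((at,h2),(g2,h1)),g1)": "ASTERACEAE",
 "(((at,h2),g1),(g2,h1))": "ASTERACEAE",
 "(((at,h2),g2),(g1,h1))": "ASTERACEAE",
 "(((at,h2),h1),(g1,g2))": "LINEAGE",
 "(((g1,g2),(h1,h2)),at)": "LINEAGE",
 "(((g1,g2),at),(h1,h2))": "LINEAGE",
 "(((g1,g2),h1),(at,h2))": "LINEAGE",
 "(((g1,g2),h2),(at,h1))": "LINEAGE",
 "(((g1,h1),(g2,h2)),at)": "ASTERACEAE",
 "(((g1,h1),at),(g2,h2))": "ASTERACEAE",
 "(((g1,h1),g2),(at,h2))": "ASTERACEAE",
 "(((g1,h1),h2),(at,g2))": "ASTERACEAE",
 "(((g1,h2),(g2,h1)),at)": "ASTERACEAE",
 "(((g1,h2),at),(g2,h1))": "ASTERACEAE",
 "(((g1,h2),g2),(at,h1))": "ASTERACEAE",
 "(((g1,h2),h1),(at,g2))": "ASTERACEAE",
 "(((g2,h1),at),(g1,h2))": "ASTERACEAE",
 "(((g2,h1),g1),(at,h2))": "ASTERACEAE",
 "(((g2,h1),h2),(at,g1))": "ASTERACEAE",
 "(((g2,h2),at),(g1,h1))": "ASTERACEAE",
 "(((g2,h2),g1),(at,h1))": "ASTERACEAE",
 "(((g2,h2),h1),(at,g1))": "ASTERACEAE",
 "(((h1,h2),at),(g1,g2))": "LINEAGE",
 "(((h1,h2),g1),(at,g2))": "ASTERACEAE",
 "(((h1,h2),g2),(at,g1))": "ASTERACEAE"
}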