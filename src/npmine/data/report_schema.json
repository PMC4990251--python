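{
  "title": "npmine pipeline report",
  "type": "object",
  "required": ["summary", "precursors"],
  "properties": {
    "summary": {
      "type": "object",
      "required": [
        "n_transcripts",
        "n_queries",
        "n_hits",
        "n_candidate_transcripts",
        "n_reported_precursors",
        "families"
      ]
    },
    "precursors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "transcript_id",
          "best_query",
          "evalue",
          "frame",
          "orf_span",
          "signal_cleavage_after",
          "cleavage_sites",
          "peptides",
          "family",
          "confidence",
          "evidence"
        ],
        "properties": {
          "peptides": {
            "type": "array",
            "items": {
              "type": "object",
              "required": [
                "sequence",
                "span",
                "flank",
                "amidated",
                "pyroglutamate",
                "sulfated_tyr"
              ]
            }
          }
        }
      }
    }
  }
}
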