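{
  "sgd": "http://bio2rdf.org/sgd:",
  "chebi": "http://bio2rdf.org/chebi:",
  "go": "http://bio2rdf.org/go:",
  "so": "http://bio2rdf.org/so:",
  "eco": "http://bio2rdf.org/eco:",
  "pmid": "http://bio2rdf.org/pubmed:",
  "bio2rdf": "http://bio2rdf.org/",
  "hq": "http://example.org/hq/vocab#",
  "hqd": "http://example.org/hq/data#"
}
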