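{
  "emotions": {
    "anger": {
      "words": ["argue", "argued", "arguing", "argument", "angerer", "hate", "hated", "hates", "hating", "mad", "furious", "rage", "outrage"],
      "prefixes": ["abhor", "acrimon", "affront", "aggravat", "anger", "annoy", "loathe", "piss", "resent", "irritat"],
      "phrases": ["bad temper", "bent out of shape"],
      "emoticons": [">:("],
      "base_rate": 1.8
    },
    "anxiety": {
      "words": ["alarmed", "antsy", "anxious", "apprehensive", "dread", "nervous", "fear", "feared", "fearful", "fears", "afraid", "scared", "stressed", "overwhelmed", "worried", "worry", "panic"],
      "prefixes": ["alarming", "angst", "anxiet", "apprehens", "creep", "daunt", "disquiet", "distraught", "distress", "eeri", "terrif"],
      "phrases": ["on edge"],
      "emoticons": [],
      "base_rate": 2.4
    },
    "sadness": {
      "words": ["cry", "cried", "crying", "cries", "deject", "dejected", "sad", "sadness", "grief", "grieving", "mourn", "heartbroken"],
      "prefixes": ["bawl", "bereav", "bittersweet", "cheerless", "crestfallen", "depress", "gloom", "sorrow"],
      "phrases": ["bummed out", "clinical depression", "broken heart"],
      "emoticons": [":(", "):", ":'(", ":-("],
      "base_rate": 2.1
    }
  }
}
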