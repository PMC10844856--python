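{
  "wrist": {
    "WB1": ["EDA", "BVP", "TEMP"],
    "WB2": ["sweat", "EDA", "BVP"],
    "WB3": ["EDA", "BVP"]
  },
  "chest": {
    "CB1": ["ECG", "RESP", "EMG", "EDA", "TEMP"],
    "CB2": ["sweat", "ECG", "RESP", "EMG", "TEMP"],
    "CB3": ["sweat", "ECG", "RESP", "EMG"],
    "CB4": ["sweat", "ECG", "RESP", "EMG"],
    "CB5": ["sweat", "ECG", "RESP", "EDA"],
    "CB6": ["sweat", "ECG", "EMG", "TEMP"],
    "CB7": ["sweat", "ECG", "EMG", "EDA"],
    "CB8": ["sweat", "RESP", "EDA", "TEMP"],
    "CB9": ["sweat", "ECG", "EDA", "TEMP"],
    "CB10": ["ECG", "RESP", "EMG", "TEMP"],
    "CB11": ["ECG", "RESP", "EMG", "TEMP"],
    "CB12": ["ECG", "EMG", "EDA", "TEMP"],
    "CB13": ["ECG", "RESP", "EDA", "TEMP"],
    "CB14": ["RESP", "EMG", "EDA", "TEMP"],
    "CB15": ["sweat", "EDA", "TEMP"],
    "CB16": ["sweat", "EMG", "EDA"],
    "CB17": ["sweat", "RESP", "EDA"],
    "CB18": ["sweat", "ECG", "RESP"],
    "CB19": ["sweat", "RESP", "EMG"],
    "CB20": ["sweat", "ECG", "EDA"],
    "CB21": ["ECG", "RESP", "EMG"],
    "CB22": ["ECG", "EDA", "TEMP"],
    "CB23": ["ECG", "RESP", "EDA"],
    "CB24": ["ECG", "EMG", "EDA"],
    "CB25": ["RESP", "EMG", "EDA"],
    "CB26": ["RESP", "EDA", "TEMP"],
    "CB27": ["EMG", "EDA", "TEMP"],
    "CB28": ["sweat", "RESP"]
  }
}
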