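"""Group survey respondents by age and summarise their exercise habits.

Each respondent reports age, gender, pandemic-era exercise change, and
exercise frequency/duration categories. Monthly physical activity is the
product of category midpoints and is dichotomised at the recommended
240 min/month into insufficient vs regular habit.
"""

import json

from squatscore import SurveyRecord, classify_habit, monthly_minutes, summarize

records = [
    SurveyRecord(25, "men", "decreased", "over 5 times/week", "over 60 min"),
    SurveyRecord(31, "women", "increased", "3-4 times/week", "30-50 min"),
    SurveyRecord(47, "women", "not_changed", "1-2 times/week", "10-20 min"),
    SurveyRecord(52, "men", "decreased", "1-2 times/month", "less than 5 min"),
    SurveyRecord(68, "women", "not_changed", "1-2 times/week", "30-50 min"),
    SurveyRecord(75, "men", "increased", "over 5 times/week", "30-50 min"),
]

for r in records[:3]:
    mins = monthly_minutes(r.freq_category, r.duration_category)
    print(f"age {r.age:>2.0f}: ~{mins:6.1f} min/month -> {classify_habit(mins)} exercise habit")

print()
print(json.dumps(summarize(records).to_dict(), indent=2))

# Per age group (younger <=39 y, middle 40-59 y, older >=60 y) the summary
# reports headcounts and percentages by gender, exercise change and habit;
# percentages within a category sum to 100 up to rounding.
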