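# Synthetic health-tip pool: 54 one-way educational messages in 11 topic
# subsets, mirroring the shape of a sickle-cell adolescent tip library.
# All content is invented fixture text.

[hydration]
Drink water regularly through the day - staying hydrated helps keep your blood flowing smoothly.
Carry a water bottle to school so you can sip between classes.
Warm drinks count too! Tea or warm water help you stay hydrated on cold days.
If your urine looks dark, that is a sign to drink more fluids.
Aim for a glass of water with every meal and snack.

[pain-management]
If pain starts, tell an adult early - treating pain sooner usually works better.
A warm bath or heating pad can ease mild aches at home.
Gentle stretching can help with stiffness, but rest when your body asks for it.
Keep your pain medicine where you can find it, and know your dose.
Rate your pain from 1 to 10 - it helps your care team pick the right treatment.

[temperature]
Dress in layers in winter - getting chilled can trigger a pain episode.
Avoid swimming in very cold water; pick heated pools when you can.
In summer heat, rest in the shade and drink extra fluids.
Warm up slowly after coming in from the cold.

[medication]
Take your daily medicines at the same time each day to build the habit.
Set a phone alarm for your medication time.
Never skip doses without talking to your care team first.
Refill prescriptions a week before they run out.
Bring your medicine list to every clinic visit.

[school]
Tell a teacher or school nurse if you start feeling pain at school.
Keep a water bottle and a snack in your backpack.
Ask for bathroom passes - drinking more water means more breaks, and that is okay.
A 504 plan can give you the supports you need in class - ask your family about it.
Plan ahead for gym class: hydrate first and pace yourself.

[rest]
Aim for at least 8 hours of sleep - your body repairs itself at night.
Short rest breaks during busy days help prevent crises.
Keep screens off for the last half hour before bed to fall asleep faster.
A steady bedtime, even on weekends, keeps your energy up.
Feeling worn out is a signal - slow down and rest.

[nutrition]
Eat colorful fruits and vegetables every day for vitamins your blood needs.
Foods with folate, like beans and leafy greens, help your body make new blood cells.
A balanced breakfast gives you energy for the whole morning.
Healthy snacks like nuts or yogurt beat sugary ones for steady energy.
Ask your care team whether you should take a daily vitamin.

[infection-prevention]
Wash your hands before eating and after using the bathroom.
Stay up to date on your vaccines - they protect you from serious infections.
A fever of 101 F or higher is an emergency - get medical help right away.
Avoid close contact with people who are sick when you can.
Clean small cuts right away and cover them with a bandage.

[emotional-health]
It is okay to feel frustrated about your illness - talking about it helps.
Keeping a journal can help you notice what makes good days good.
Stay connected with friends, even on days you need to rest.
Deep slow breathing can calm both stress and pain.
Ask your care team about support groups for teens like you.

[exercise]
Light exercise like walking keeps you strong - just avoid overdoing it.
Drink water before, during, and after any activity.
Stop and rest if you feel short of breath or your joints ache.
Stretching every morning keeps your muscles loose.
Choose activities you can pace yourself in, like biking or swimming in warm pools.

[transition-to-adult-care]
Learn the names and doses of your medicines - it is a big step toward independence.
Practice telling your own health story: what helps you and what to avoid.
Keep your clinic's phone number saved in your phone.
Start keeping your own calendar of appointments.
Ask one question yourself at your next clinic visit - your voice matters.
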